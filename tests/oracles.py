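"""Independent reference implementations used only to validate results."""

from functools import lru_cache

from domfact.translated_search import _blosum62


def brute_force_local_score(a: str, b: str, gap_open: int = 11,
                            gap_extend: int = 1) -> int:
    """Best local score by exhaustive recursion over alignment op sequences,
    maximised over all substring pairs — independent of the DP kernel."""
    sub, idx = _blosum62()

    @lru_cache(maxsize=None)
    def glob(i, j, ai, aj, last):
        if i == ai and j == aj:
            return 0
        best = -(10**9)
        if i < ai and j < aj:
            best = max(best, int(sub[idx[a[i]], idx[b[j]]])
                       + glob(i + 1, j + 1, ai, aj, "M"))
        if i < ai:
            best = max(best, -(gap_extend if last == "D" else gap_open + gap_extend)
                       + glob(i + 1, j, ai, aj, "D"))
        if j < aj:
            best = max(best, -(gap_extend if last == "I" else gap_open + gap_extend)
                       + glob(i, j + 1, ai, aj, "I"))
        return best

    best = 0
    for i in range(len(a)):
        for ai in range(i + 1, len(a) + 1):
            for j in range(len(b)):
                for aj in range(j + 1, len(b) + 1):
                    best = max(best, glob(i, j, ai, aj, "S"))
    return best
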