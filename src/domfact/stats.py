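"""Post-verdict statistics: per-species summaries, ordinal position of
events, rank correlations with assembly-quality metrics, paired tests, and
phylogenetic generalized least squares (PGLS) against patristic distance.

All table-style ratios and percentages use half-away-from-zero rounding to
one decimal, the convention of the per-species report tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
from scipy import optimize
from scipy import stats as sps

from .content import DomainContent
from .events import AD, MD, OrthologPair
from .factcheck import (
    ANN_ORTHO,
    ANN_REF,
    GENE_PRED,
    ISOFORM,
    SWITCHING,
    TRUE_AD,
    TRUE_MD,
    UNDET_GENOME,
    Verdict,
)


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (3.65 -> 3.7, -3.65 -> -3.7)."""
    if not math.isfinite(value):
        raise ValueError("non-finite value")
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


@dataclass
class StatResult:
    name: str
    estimate: float
    df: float
    p_value: float
    n: int
    extra: dict = field(default_factory=dict)


@dataclass
class SpeciesSummary:
    """Per-species, ortholog-level tallies of verdict classes.

    The per-direction identity ``potential = annotation + gene/isoform +
    undetermined + switching + true`` holds by construction: each ortholog
    contributes once per direction, in the class of its highest-precedence
    verdict for that direction.
    """

    species: str
    n_orthologs: int = 0
    potential_md: int = 0
    potential_ad: int = 0
    md_annotation: int = 0  # annotation_inconsistent_* (either side)
    md_gene_prediction: int = 0
    md_undetermined: int = 0
    md_switching: int = 0
    true_md: int = 0
    ad_annotation: int = 0
    ad_isoform: int = 0
    ad_switching: int = 0
    true_ad: int = 0

    @property
    def ratio_md_ad(self) -> Optional[float]:
        if self.potential_ad == 0:
            return None
        return round_half_away(self.potential_md / self.potential_ad, 1)

    @property
    def pct_true_md(self) -> Optional[float]:
        if self.potential_md == 0:
            return None
        return round_half_away(100.0 * self.true_md / self.potential_md, 1)

    @property
    def pct_true_ad(self) -> Optional[float]:
        if self.potential_ad == 0:
            return None
        return round_half_away(100.0 * self.true_ad / self.potential_ad, 1)

    @property
    def pct_orthologs_with_events(self) -> Optional[float]:
        if self.n_orthologs == 0:
            return None
        return round_half_away(
            100.0 * (self.potential_md + self.potential_ad) / self.n_orthologs, 1
        )


# precedence used to assign an ortholog with several same-direction verdicts
# to a single class column (errors dominate true events)
_CLASS_RANK = {
    ANN_ORTHO: 0,
    ANN_REF: 0,
    GENE_PRED: 1,
    ISOFORM: 1,
    UNDET_GENOME: 2,
    SWITCHING: 3,
    TRUE_MD: 4,
    TRUE_AD: 4,
}


def summarize(
    verdicts: Sequence[Verdict],
    pairs: Sequence[OrthologPair],
    include_total: bool = True,
) -> dict[str, SpeciesSummary]:
    """Ortholog-level per-species summary of fact-check outcomes.

    An ortholog with several events in one direction is counted once for
    that direction, under its highest-precedence class (annotation < gene/
    isoform < undetermined < switching < true).  Event-level counts are
    available from the verdict list itself.
    """
    out: dict[str, SpeciesSummary] = {}
    for p in pairs:
        s = out.setdefault(p.species, SpeciesSummary(p.species))
        s.n_orthologs += 1
    # (species, ortho, direction) -> best class
    best: dict[tuple[str, str, str], str] = {}
    for v in verdicts:
        key = (v.event.pair.species, v.event.pair.ortho_id, v.event.direction)
        prev = best.get(key)
        if prev is None or _CLASS_RANK[v.klass] < _CLASS_RANK[prev]:
            best[key] = v.klass
    for (species, _ortho, direction), klass in best.items():
        s = out.setdefault(species, SpeciesSummary(species))
        if direction == MD:
            s.potential_md += 1
            if klass in (ANN_ORTHO, ANN_REF):
                s.md_annotation += 1
            elif klass == GENE_PRED:
                s.md_gene_prediction += 1
            elif klass == UNDET_GENOME:
                s.md_undetermined += 1
            elif klass == SWITCHING:
                s.md_switching += 1
            else:
                s.true_md += 1
        else:
            s.potential_ad += 1
            if klass in (ANN_ORTHO, ANN_REF):
                s.ad_annotation += 1
            elif klass == ISOFORM:
                s.ad_isoform += 1
            elif klass == SWITCHING:
                s.ad_switching += 1
            else:
                s.true_ad += 1
    if include_total and out:
        total = SpeciesSummary("Total")
        for s in out.values():
            for f in (
                "n_orthologs",
                "potential_md",
                "potential_ad",
                "md_annotation",
                "md_gene_prediction",
                "md_undetermined",
                "md_switching",
                "true_md",
                "ad_annotation",
                "ad_isoform",
                "ad_switching",
                "true_ad",
            ):
                setattr(total, f, getattr(total, f) + getattr(s, f))
        out["Total"] = total
    return out


# ---------------------------------------------------------------------------
# ordinal position analysis

N_TERMINAL = "N_terminal"
C_TERMINAL = "C_terminal"
INTERNAL = "internal"


def ordinal_positions(
    true_verdicts: Sequence[Verdict],
    contents: Mapping[str, DomainContent],
) -> dict[str, dict[str, int]]:
    """Classify true events as N-terminal, C-terminal or internal.

    Only ortholog pairs where *both* proteins have at least two units are
    eligible; the ordinal index is taken on the protein that carries the
    unit (the reference for MD, the ortholog for AD).  Returns counts per
    direction.
    """
    counts = {MD: {N_TERMINAL: 0, INTERNAL: 0, C_TERMINAL: 0},
              AD: {N_TERMINAL: 0, INTERNAL: 0, C_TERMINAL: 0}}
    for v in true_verdicts:
        if v.klass not in (TRUE_MD, TRUE_AD):
            continue
        ev = v.event
        ref_c = contents.get(ev.pair.ref_id)
        ortho_c = contents.get(ev.pair.ortho_id)
        if ref_c is None or ortho_c is None:
            continue
        if len(ref_c) < 2 or len(ortho_c) < 2:
            continue
        carrier = ref_c if ev.direction == MD else ortho_c
        ordered = carrier.ordered_units()
        idx = next(
            (i for i, u in enumerate(ordered) if u.intersects(ev.unit)), None
        )
        if idx is None:
            continue
        if idx == 0:
            pos = N_TERMINAL
        elif idx == len(ordered) - 1:
            pos = C_TERMINAL
        else:
            pos = INTERNAL
        counts[ev.direction][pos] += 1
    return counts


# ---------------------------------------------------------------------------
# correlations and tests


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    exact: bool = False,
) -> StatResult:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of mid-ranks; the two-sided p-value uses
    the t approximation with df = n - 2.  With ``exact=True`` (n <= 10) the
    p-value is computed by full permutation of one rank vector instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    if np.std(rx) == 0 or np.std(ry) == 0:
        return StatResult("spearman", float("nan"), n - 2, float("nan"), n)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only for n <= 10")
        from itertools import permutations

        obs = abs(rho)
        count = total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        return StatResult("spearman", rho, n - 2, count / total, n)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho**2))
        p = 2 * sps.t.sf(abs(t), n - 2)
    return StatResult("spearman", rho, n - 2, p, n)


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Classical paired t-test on the differences a - b, df = n - 1.

    Zero variance of the differences with zero mean returns t = 0, p = 1
    (documented convention); zero variance with nonzero mean is NA.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length vectors")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return StatResult("paired_t", 0.0, n - 1, 1.0, n)
        return StatResult("paired_t", float("nan"), n - 1, float("nan"), n)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return StatResult("paired_t", float(t), n - 1, float(p), n)


# ---------------------------------------------------------------------------
# phylogenetics: patristic distances and PGLS


@dataclass
class PhyloDistances:
    species: list[str]
    distance_to_ref: dict[str, float]
    tree: dendropy.Tree


def load_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def patristic_distances(tree: dendropy.Tree, reference: str) -> PhyloDistances:
    """Sum of branch lengths from each non-reference tip to the reference."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    if reference not in taxa:
        raise ValueError(f"reference taxon {reference!r} not in tree")
    ref = taxa[reference]
    dists = {}
    for label, taxon in taxa.items():
        if label == reference:
            continue
        d = float(pdm.patristic_distance(ref, taxon))
        if d <= 0:
            raise ValueError(f"non-positive patristic distance for {label}")
        dists[label] = d
    return PhyloDistances(sorted(dists), dists, tree)


def phylo_vcv(tree: dendropy.Tree, species: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-MRCA branch length."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in species if s not in taxa]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    root_dist = {}
    for leaf in tree.leaf_node_iter():
        root_dist[leaf.taxon.label] = float(leaf.distance_from_root())
    n = len(species)
    V = np.empty((n, n))
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            if i == j:
                V[i, j] = root_dist[a]
            else:
                d = float(pdm.patristic_distance(taxa[a], taxa[b]))
                V[i, j] = 0.5 * (root_dist[a] + root_dist[b] - d)
    return V


def _lambda_vcv(V: np.ndarray, lam: float) -> np.ndarray:
    Vl = lam * V
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


def _gls(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    n = len(y)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular phylogenetic covariance (duplicate zero-length tips?)"
        ) from exc
    # whiten by the Cholesky factor
    from scipy.linalg import solve_triangular

    Xs = solve_triangular(L, X, lower=True)
    ys = solve_triangular(L, y, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    cov_beta = sigma2 * n / (n - X.shape[1]) * np.linalg.inv(Xs.T @ Xs)
    return beta, rss, ll, cov_beta, Xs, ys


def pgls_fit(
    dist: PhyloDistances,
    y: Sequence[float],
    species: Optional[Sequence[str]] = None,
    lam: Optional[float] = None,
    x: Optional[Sequence[float]] = None,
) -> StatResult:
    """PGLS of y on patristic distance to the reference, Pagel-lambda model.

    The error covariance is the Brownian shared-branch-length matrix with
    off-diagonals scaled by lambda; delta and kappa are fixed at 1 (branch
    lengths used as given).  lambda is estimated by bounded ML on [0, 1]
    (tolerance 1e-6) unless fixed via ``lam``.  An explicit covariate ``x``
    (e.g. an assembly-quality metric) replaces the default distance
    regressor.  Returns R-squared as the estimate, with slope, its SE, and
    lambda-hat in ``extra``; the p-value is the F-test of the slope with
    df = (1, n - 2).
    """
    sp = list(species) if species is not None else dist.species
    y = np.asarray(y, dtype=float)
    if len(y) != len(sp):
        raise ValueError("y length does not match species list")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    if x is None:
        x = np.array([dist.distance_to_ref[s] for s in sp])
    else:
        x = np.asarray(x, dtype=float)
        if len(x) != len(sp):
            raise ValueError("x length does not match species list")
    V = phylo_vcv(dist.tree, sp)
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    X0 = np.ones((n, 1))

    def negll(l: float) -> float:
        _, _, ll, _, _, _ = _gls(X, y, _lambda_vcv(V, l))
        return -ll

    if lam is None:
        res = optimize.minimize_scalar(
            negll, bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-6},
        )
        lam_hat = float(res.x)
        # the bounded search can stall just inside the boundary
        for bound in (0.0, 1.0):
            if negll(bound) <= negll(lam_hat):
                lam_hat = bound
    else:
        lam_hat = float(lam)
    Vl = _lambda_vcv(V, lam_hat)
    beta, rss, ll, cov_beta, _, _ = _gls(X, y, Vl)
    _, rss0, _, _, _, _ = _gls(X0, y, Vl)
    r2 = 1.0 - rss / rss0 if rss0 > 0 else float("nan")
    if n > 2 and rss > 0:
        F = (rss0 - rss) / (rss / (n - 2))
        p = float(sps.f.sf(F, 1, n - 2))
    else:
        p = float("nan")
    slope_se = float(np.sqrt(cov_beta[1, 1]))
    return StatResult(
        "pgls",
        estimate=float(r2),
        df=n - 2,
        p_value=p,
        n=n,
        extra={
            "lambda": lam_hat,
            "slope": float(beta[1]),
            "intercept": float(beta[0]),
            "slope_se": slope_se,
            "loglik": float(ll),
        },
    )
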