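"""Compositionality-aware correlation inference (SparCC-style).

Sequencing depths are compositional: per-sample totals are arbitrary, so
Pearson correlations of raw counts are distorted by the closure.  The
estimator implemented here recovers correlations between the unobserved
("basis") absolute abundances from the observable log-ratio variances

    t_ij = Var_samples[ log(f_i / f_j) ]

where ``f`` are per-sample fractions.  Under the decomposition
``t_ij = w_i^2 + w_j^2 - 2 rho_ij w_i w_j`` and a sparsity assumption
(most pairs uncorrelated), the basis variances ``w_i^2`` solve the linear
system obtained by summing t over partners, and

    rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j) .

Strongly correlated pairs violate the sparsity assumption, so the strongest
pair is iteratively excluded from the sums and the system re-solved.

Edge significance uses permutation pseudo-p values: each OTU's sample
labels are shuffled independently, the whole estimator is recomputed, and
the two-sided p value is the fraction of permutations whose null |rho|
reaches the observed one (resolution 1 / n_permutations).

The estimator is exposed both as plain functions and as the
``SparCC(counts).fit() -> SparCCResults`` model/results pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import stream

OMEGA_FLOOR = 1e-12


@dataclass
class FractionEstimate:
    """Per-sample component fractions (columns sum to 1).

    ``presence`` records which counts were positive: zeros in the depth
    table are structural (the organism is absent from the sample), so a
    pair's log-ratio variance is estimated over co-observed samples only.
    """

    fractions: np.ndarray            # deterministic point estimate, D x n
    draws: list[np.ndarray] = field(default_factory=list)  # Dirichlet resamples
    pseudocount: float = 1.0
    n_resamples: int = 0
    presence: np.ndarray | None = None  # D x n boolean


@dataclass
class BasisEstimate:
    t: np.ndarray                    # log-ratio variance matrix, D x D
    omega_sq: np.ndarray             # basis variances, length D
    rho: np.ndarray                  # basis correlations, D x D, in [-1, 1]
    excluded_pairs: set[tuple[int, int]] = field(default_factory=set)
    n_exclusion_iters: int = 0


def estimate_fractions(
    counts: pd.DataFrame | np.ndarray,
    pseudocount: float = 1.0,
    n_resamples: int = 20,
    seed: int = 0,
) -> FractionEstimate:
    """Counts -> per-sample fractions, optionally with Dirichlet resamples.

    The point estimate is (count + pseudocount) column-normalized.  With
    ``n_resamples > 0``, posterior fractions are drawn per sample from
    Dirichlet(count + 1); downstream basis estimates are averaged over the
    draws.  All-zero columns become uniform under the pseudocount.
    """
    x = np.asarray(counts, dtype=float)
    d, n = x.shape
    if d < 4:
        raise ValueError(
            f"need at least 4 components for basis-variance identifiability, got {d}"
        )
    if n < 3:
        raise ValueError("need at least 3 samples")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    point = x + pseudocount
    point /= point.sum(axis=0, keepdims=True)
    draws = []
    if n_resamples > 0:
        rng = stream(seed, "sparcc.dirichlet")
        for _ in range(n_resamples):
            f = np.empty_like(point)
            for j in range(n):
                f[:, j] = rng.dirichlet(x[:, j] + 1.0)
            draws.append(f)
    return FractionEstimate(point, draws, pseudocount, n_resamples, presence=x > 0)


def log_ratio_variance(
    fractions: np.ndarray, presence: np.ndarray | None = None
) -> np.ndarray:
    """t_ij = variance over samples of log(f_i / f_j) (unbiased, ddof=1).

    With a ``presence`` mask, each pair's variance uses only samples where
    both components were actually observed — a structural zero carries no
    information about the ratio.  Pairs with fewer than 3 co-observed
    samples fall back to all samples.
    """
    logf = np.log(fractions)
    d = logf.shape[0]
    t = np.zeros((d, d))
    if presence is None or bool(presence.all()):
        for i in range(d):
            diff = logf[i] - logf
            t[i] = diff.var(axis=1, ddof=1)
    else:
        for i in range(d):
            for j in range(i + 1, d):
                both = presence[i] & presence[j]
                diff = logf[i, both] - logf[j, both] if both.sum() >= 3 else logf[i] - logf[j]
                t[i, j] = t[j, i] = diff.var(ddof=1)
    np.fill_diagonal(t, 0.0)
    return (t + t.T) / 2.0


def _solve_basis(t: np.ndarray, excluded: set[tuple[int, int]]) -> np.ndarray:
    """Solve t_i = n_i w_i^2 + sum_{j in kept(i)} w_j^2 for the basis variances.

    With no exclusions this is the closed form
    w_i^2 = (t_i - W) / (D - 2), W = sum_i t_i / (2(D-1)).
    """
    d = t.shape[0]
    if d <= 2:
        raise ValueError("basis variances undefined for D <= 2")
    keep = np.ones((d, d), dtype=bool)
    np.fill_diagonal(keep, False)
    for i, j in excluded:
        keep[i, j] = keep[j, i] = False
    a = keep.astype(float)
    a[np.diag_indices(d)] = keep.sum(axis=1)
    rhs = (t * keep).sum(axis=1)
    omega_sq = np.linalg.solve(a, rhs)
    if (omega_sq < OMEGA_FLOOR).any():
        warnings.warn(
            "negative basis variance floored; estimates for the affected "
            "components are unreliable",
            RuntimeWarning,
            stacklevel=3,
        )
        omega_sq = np.maximum(omega_sq, OMEGA_FLOOR)
    return omega_sq


def _rho_from(t: np.ndarray, omega_sq: np.ndarray) -> np.ndarray:
    w = np.sqrt(omega_sq)
    rho = (omega_sq[:, None] + omega_sq[None, :] - t) / (2.0 * np.outer(w, w))
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def basis_correlations(
    fractions: FractionEstimate | np.ndarray,
    exclusion_threshold: float = 0.1,
    max_exclusion_iters: int = 10,
) -> BasisEstimate:
    """Estimate basis variances and correlations with iterative pair exclusion.

    One pair — the currently strongest |rho| above ``exclusion_threshold`` —
    is excluded per iteration and the variance system re-solved, up to
    ``max_exclusion_iters`` times.  When a :class:`FractionEstimate` carries
    Dirichlet draws, the estimate is the average over draws (t and rho
    averaged; omega re-derived from the averaged t).
    """
    if isinstance(fractions, FractionEstimate) and fractions.draws:
        singles = [
            basis_correlations(
                FractionEstimate(f, pseudocount=fractions.pseudocount, presence=fractions.presence),
                exclusion_threshold,
                max_exclusion_iters,
            )
            for f in fractions.draws
        ]
        t = np.mean([s.t for s in singles], axis=0)
        rho = np.mean([s.rho for s in singles], axis=0)
        omega = np.mean([s.omega_sq for s in singles], axis=0)
        excluded = set().union(*(s.excluded_pairs for s in singles))
        rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        return BasisEstimate(t, omega, rho, excluded, max(s.n_exclusion_iters for s in singles))

    if isinstance(fractions, FractionEstimate):
        f, presence = fractions.fractions, fractions.presence
    else:
        f, presence = np.asarray(fractions), None
    t = log_ratio_variance(f, presence)
    excluded: set[tuple[int, int]] = set()
    omega_sq = _solve_basis(t, excluded)
    rho = _rho_from(t, omega_sq)
    iters = 0
    d = t.shape[0]
    for _ in range(max_exclusion_iters):
        # strongest not-yet-excluded off-diagonal pair
        mask = np.ones((d, d), dtype=bool)
        np.fill_diagonal(mask, False)
        for i, j in excluded:
            mask[i, j] = mask[j, i] = False
        abs_rho = np.where(mask, np.abs(rho), -np.inf)
        i, j = np.unravel_index(int(np.argmax(abs_rho)), rho.shape)
        if abs_rho[i, j] <= exclusion_threshold:
            break
        # never disconnect a component from the system entirely
        kept_i = mask[i].sum() - 1
        kept_j = mask[j].sum() - 1
        if kept_i < 2 or kept_j < 2:
            break
        excluded.add((int(min(i, j)), int(max(i, j))))
        omega_sq = _solve_basis(t, excluded)
        rho = _rho_from(t, omega_sq)
        iters += 1
    return BasisEstimate(t, omega_sq, rho, excluded, iters)


def pseudo_p(
    counts: pd.DataFrame | np.ndarray,
    rho_observed: np.ndarray,
    n_permutations: int = 100,
    seed: int = 0,
    pseudocount: float = 1.0,
    include_identity: bool = False,
) -> np.ndarray:
    """Two-sided permutation pseudo-p values for every OTU pair.

    Each permutation shuffles every OTU's depths across samples
    independently and recomputes the full basis-correlation matrix (with
    the deterministic fraction estimate; the null does not need posterior
    resampling).  ``include_identity`` adds the unpermuted table as one
    permutation, bounding every p away from zero (sanity mode).
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    x = np.asarray(counts, dtype=float)
    d, n = x.shape
    rng = stream(seed, "sparcc.permute")
    hits = np.zeros((d, d))
    obs = np.abs(rho_observed)
    total = 0
    if include_identity:
        hits += (obs >= obs).astype(float)
        total += 1
    for _ in range(n_permutations - int(include_identity)):
        perm = np.empty_like(x)
        for i in range(d):
            perm[i] = x[i, rng.permutation(n)]
        fe = estimate_fractions(perm, pseudocount=pseudocount, n_resamples=0)
        with warnings.catch_warnings():
            # permuted tables routinely trip the variance floor; that is the
            # null doing its job, not a condition to report
            warnings.simplefilter("ignore", RuntimeWarning)
            null = basis_correlations(fe)
        hits += (np.abs(null.rho) >= obs).astype(float)
        total += 1
    p = hits / total
    np.fill_diagonal(p, np.nan)
    return p


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class SparCC:
    """Basis-correlation model over an OTU x sample count table.

    Parameters
    ----------
    counts
        Non-negative OTU x sample depth table (rows OTUs, columns samples).
    pseudocount, n_resamples, exclusion_threshold, max_exclusion_iters
        Estimator knobs; the defaults match common practice for the
        published estimator.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        pseudocount: float = 1.0,
        n_resamples: int = 20,
        exclusion_threshold: float = 0.1,
        max_exclusion_iters: int = 10,
    ) -> None:
        if not isinstance(counts, pd.DataFrame):
            counts = pd.DataFrame(np.asarray(counts))
        self.counts = counts
        self.pseudocount = pseudocount
        self.n_resamples = n_resamples
        self.exclusion_threshold = exclusion_threshold
        self.max_exclusion_iters = max_exclusion_iters

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, **kwargs) -> "SparCC":
        return cls(counts, **kwargs)

    def fit(self, n_permutations: int = 100, seed: int = 0) -> "SparCCResults":
        fe = estimate_fractions(
            self.counts, self.pseudocount, self.n_resamples, seed=seed
        )
        basis = basis_correlations(fe, self.exclusion_threshold, self.max_exclusion_iters)
        p = pseudo_p(
            self.counts,
            basis.rho,
            n_permutations=n_permutations,
            seed=seed,
            pseudocount=self.pseudocount,
        )
        return SparCCResults(self, basis, p, n_permutations, seed)


class SparCCResults:
    """Fitted basis correlations with permutation significance."""

    def __init__(
        self,
        model: SparCC,
        basis: BasisEstimate,
        p: np.ndarray,
        n_permutations: int,
        seed: int,
    ) -> None:
        self.model = model
        self.basis = basis
        self.n_permutations = n_permutations
        self.seed = seed
        ids = list(model.counts.index)
        self.otu_ids = ids
        self.rho = pd.DataFrame(basis.rho, index=ids, columns=ids)
        self.pvalues = pd.DataFrame(p, index=ids, columns=ids)
        self.omega_sq = pd.Series(basis.omega_sq, index=ids, name="omega_sq")

    def summary(self, top: int = 10) -> str:
        d = len(self.otu_ids)
        iu = np.triu_indices(d, k=1)
        rho = self.rho.to_numpy()[iu]
        p = self.pvalues.to_numpy()[iu]
        order = np.argsort(-np.abs(rho))[:top]
        lines = [
            "Basis correlation model (SparCC-type)",
            f"  components: {d}   samples: {self.model.counts.shape[1]}",
            f"  Dirichlet resamples: {self.model.n_resamples}   "
            f"permutations: {self.n_permutations}   seed: {self.seed}",
            f"  excluded pairs: {len(self.basis.excluded_pairs)}",
            "",
            f"  {'pair':<24}{'rho':>8}{'pseudo-p':>10}",
        ]
        for k in order:
            i, j = iu[0][k], iu[1][k]
            lines.append(
                f"  {self.otu_ids[i]} ~ {self.otu_ids[j]:<12}"
                f"{rho[k]:>8.3f}{p[k]:>10.3f}"
            )
        return "\n".join(lines)
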