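"""Two-step hypergeometric enrichment for co-regulatory TF discovery.

Given a focal TF's target-gene set and a pool of ChIP-Seq profiles (one
target set per experiment, many experiments per TF), the method first
scores every profile for overlap with the focal targets by an upper-tail
hypergeometric test, keeps the most significant profiles (p < alpha,
truncated to the top ``max_profiles``), and then asks, per TF, whether
that TF's profiles are over-represented among the selected ones — again
by an upper-tail hypergeometric test, this time drawing profiles rather
than genes.  A TF is called a co-factor when its step-2 p-value passes
``alpha`` and it contributes at least ``min_sig`` significant profiles.

The upper-tail probability is computed in log space (lgamma binomial
coefficients + logsumexp) so that gene universes of any realistic size
are handled without overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from tfnetminer.models import ChipProfile


@dataclass(frozen=True)
class OverlapCounts:
    """Urn counts for one overlap test.

    n_total genes in the universe, of which n_focal are the focal TF's
    targets; n_profile genes drawn by the other profile; n_overlap shared.
    """

    n_total: int
    n_profile: int
    n_focal: int
    n_overlap: int

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_profile, self.n_focal, self.n_overlap) < 0:
            raise ValueError("overlap counts must be non-negative")
        if max(self.n_profile, self.n_focal) > self.n_total:
            raise ValueError("category counts exceed the universe size")
        if self.n_overlap > min(self.n_profile, self.n_focal):
            raise ValueError(
                f"overlap {self.n_overlap} exceeds min(n_profile, n_focal)="
                f"{min(self.n_profile, self.n_focal)}"
            )


@dataclass(frozen=True)
class ProfileEnrichment:
    profile_id: str
    tf_name: str
    counts: OverlapCounts
    p: float


@dataclass
class SigProfileSet:
    """Profiles passing step 1, most significant first."""

    profiles: list[ProfileEnrichment] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return len(self.profiles)

    @property
    def profile_ids(self) -> set[str]:
        return {p.profile_id for p in self.profiles}


@dataclass(frozen=True)
class TFEnrichment:
    tf_name: str
    n_profiles_pool: int
    n_profiles_sig: int
    p: float
    called: bool


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def upper_tail_curve(n_total: int, n_focal: int, n_profile: int) -> np.ndarray:
    """Upper-tail p for every possible overlap value at once.

    Returns an array ``tail`` of length ``min(n_profile, n_focal) + 1``
    with ``tail[s] = P(overlap >= s)`` under the hypergeometric null.
    Computed from log pmf terms with a reverse log-cumulative-sum-exp.
    """
    hi = min(n_profile, n_focal)
    lo = max(0, n_profile + n_focal - n_total)
    s = np.arange(lo, hi + 1)
    log_pmf = (
        _log_binom(n_focal, s)
        + _log_binom(n_total - n_focal, n_profile - s)
        - _log_binom(n_total, n_profile)
    )
    # reverse logcumsumexp over the support, padded with -inf below lo
    tail_support = np.empty_like(log_pmf)
    acc = -np.inf
    for i in range(len(s) - 1, -1, -1):
        acc = np.logaddexp(acc, log_pmf[i])
        tail_support[i] = acc
    tail = np.zeros(hi + 1)
    tail[lo:] = np.minimum(np.exp(tail_support), 1.0)
    tail[: lo + 1] = 1.0  # overlap >= lo is certain
    return np.clip(tail, np.finfo(float).tiny, 1.0)


def hypergeom_upper_tail(counts: OverlapCounts) -> float:
    """P(overlap >= observed) when drawing without replacement.

    Sums the hypergeometric pmf from the observed overlap up to
    min(n_profile, n_focal), in log space; the result is clipped to (0, 1].
    """
    hi = min(counts.n_profile, counts.n_focal)
    lo = max(0, counts.n_profile + counts.n_focal - counts.n_total)
    if counts.n_overlap <= lo:
        return 1.0  # the whole support lies in the tail
    s = np.arange(counts.n_overlap, hi + 1)
    log_terms = (
        _log_binom(counts.n_focal, s)
        + _log_binom(counts.n_total - counts.n_focal, counts.n_profile - s)
        - _log_binom(counts.n_total, counts.n_profile)
    )
    p = float(np.exp(logsumexp(log_terms)))
    return min(max(p, np.finfo(float).tiny), 1.0)


def step1_select(
    pool: list[ChipProfile],
    focal_targets: set[str],
    universe: set[str],
    max_profiles: int = 50,
    alpha: float = 0.01,
) -> SigProfileSet:
    """Select the significantly overlapping profiles ("sig" set).

    Profile and focal target sets are intersected with ``universe`` before
    counting.  Profiles with p < ``alpha`` are ranked by ascending p (ties
    broken by profile id) and truncated to ``max_profiles``.
    """
    if not universe:
        raise ValueError("empty gene universe")
    focal = set(focal_targets) & universe
    if not focal <= universe:
        raise ValueError("focal targets not contained in universe")
    n_total, n_focal = len(universe), len(focal)
    hits: list[ProfileEnrichment] = []
    for prof in pool:
        targets = prof.targets & universe
        counts = OverlapCounts(n_total, len(targets), n_focal, len(targets & focal))
        p = hypergeom_upper_tail(counts)
        if p < alpha:
            hits.append(ProfileEnrichment(prof.profile_id, prof.tf_name, counts, p))
    hits.sort(key=lambda e: (e.p, e.profile_id))
    return SigProfileSet(hits[:max_profiles])


def step2_tf_enrichment(
    sig: SigProfileSet,
    pool: list[ChipProfile],
    alpha: float = 0.01,
    min_sig: int = 3,
) -> list[TFEnrichment]:
    """Per-TF over-representation among the step-1 profiles.

    The urn now contains profiles: universe size = |pool|, draws = the
    step-1 set, category = the TF's profiles in the pool.  A TF is
    ``called`` iff p < ``alpha`` and it has >= ``min_sig`` significant
    profiles.
    """
    pool_ids = {p.profile_id for p in pool}
    stray = sig.profile_ids - pool_ids
    if stray:
        raise ValueError(f"sig set references profiles absent from pool: {sorted(stray)[:3]}")
    n_total = len(pool)
    n_sel = sig.n_selected
    pool_per_tf: dict[str, int] = {}
    for prof in pool:
        pool_per_tf[prof.tf_name] = pool_per_tf.get(prof.tf_name, 0) + 1
    sig_per_tf: dict[str, int] = {}
    for e in sig.profiles:
        sig_per_tf[e.tf_name] = sig_per_tf.get(e.tf_name, 0) + 1
    out = []
    for tf, n_sig_tf in sig_per_tf.items():
        counts = OverlapCounts(n_total, n_sel, pool_per_tf[tf], n_sig_tf)
        p = hypergeom_upper_tail(counts)
        out.append(TFEnrichment(tf, pool_per_tf[tf], n_sig_tf, p, p < alpha and n_sig_tf >= min_sig))
    out.sort(key=lambda e: (e.p, e.tf_name))
    return out


def find_cofactors(
    pool: list[ChipProfile],
    focal_targets: set[str],
    universe: set[str],
    max_profiles: int = 50,
    alpha1: float = 0.01,
    alpha2: float = 0.01,
    min_sig: int = 3,
) -> list[TFEnrichment]:
    """Run both steps; returns all step-2 rows (called TFs flagged)."""
    sig = step1_select(pool, focal_targets, universe, max_profiles, alpha1)
    if sig.n_selected == 0:
        return []
    return step2_tf_enrichment(sig, pool, alpha2, min_sig)
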