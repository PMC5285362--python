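"""Pairwise comparison of exo-miRNA profiles: shared fractions and correlation.

The motivating heuristic: an exogenous miRNA that recurs across datasets of
the *same* laboratory (intra-study) is more plausibly a process contamination
(reagents, sample handling, index hopping), while recurrence across
*independent* laboratories (inter-study) is weak evidence for a genuine
biological source.  The comparison layer quantifies both the overlap of
presence sets and the correlation of abundance profiles, and labels each
pair intra- vs inter-study.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from exomir.errors import ValidationError, ZeroVarianceError
from exomir.exo_classify import DatasetProfile, ExoHit, compute_rpm
from exomir.reference_io import DatasetMetadata


@dataclass(frozen=True)
class ComparisonResult:
    pair: tuple[str, str]
    n_union: int
    n_shared: int
    shared_pct: float
    r: float
    p_value: float
    relation: str  # "intra_study" | "inter_study"


def _presence_set(profile: DatasetProfile, granularity: str = "id") -> set[str]:
    if granularity == "id":
        return {h.mirna_id for h in profile.hits}
    if granularity == "family":
        return {h.family_key for h in profile.hits}
    raise ValueError(f"unknown granularity {granularity!r}")


def shared_fraction(
    a: DatasetProfile, b: DatasetProfile, granularity: str = "id"
) -> tuple[int, int, float]:
    """Overlap of presence sets: (n_shared, n_union, shared percentage).

    shared_pct = 100 * |A ∩ B| / |A ∪ B|, exact (rounding is presentation
    only).  Comparing two empty profiles is undefined and raises.
    """
    sa, sb = _presence_set(a, granularity), _presence_set(b, granularity)
    union = sa | sb
    if not union:
        raise ValidationError("shared fraction undefined: both profiles empty")
    shared = sa & sb
    return len(shared), len(union), 100.0 * len(shared) / len(union)


def _abundance_vectors(
    a: DatasetProfile,
    b: DatasetProfile,
    keys: str = "union",
    transform: str = "log2p1",
) -> tuple[np.ndarray, np.ndarray]:
    ra, rb = a.rpm_by_id(), b.rpm_by_id()
    if keys == "union":
        ids = sorted(set(ra) | set(rb))
    elif keys == "intersection":
        ids = sorted(set(ra) & set(rb))
    else:
        raise ValueError(f"unknown key set {keys!r}")
    va = np.array([ra.get(i, 0.0) for i in ids])
    vb = np.array([rb.get(i, 0.0) for i in ids])
    if transform == "log2p1":
        va, vb = np.log2(va + 1.0), np.log2(vb + 1.0)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    return va, vb


def profile_correlation(
    a: DatasetProfile,
    b: DatasetProfile,
    keys: str = "union",
    transform: str = "log2p1",
) -> tuple[float, float]:
    """Pearson correlation of two abundance profiles.

    Vectors are keyed by the union of observed miRNA ids (absent = 0 RPM)
    and log2(rpm+1)-transformed by default, so shared absence contributes
    and heavy-tailed abundances do not dominate.  The p-value is the exact
    two-sided t-transform of r with (n_keys - 2) degrees of freedom.
    """
    va, vb = _abundance_vectors(a, b, keys, transform)
    if len(va) < 3:
        raise ValidationError(
            f"correlation needs >= 3 keyed miRNAs, got {len(va)}"
        )
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ZeroVarianceError(
            "correlation undefined: an abundance vector is constant"
        )
    res = stats.pearsonr(va, vb)
    return float(res.statistic), float(res.pvalue)


def permutation_correlation_p(
    a: DatasetProfile,
    b: DatasetProfile,
    n_permutations: int = 10_000,
    seed: int = 0,
    keys: str = "union",
    transform: str = "log2p1",
) -> float:
    """Seeded permutation p-value for the profile correlation (two-sided),
    for small key sets where the t-approximation is doubtful."""
    va, vb = _abundance_vectors(a, b, keys, transform)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ZeroVarianceError("correlation undefined: constant vector")
    rng = np.random.default_rng(seed)
    r_obs = abs(np.corrcoef(va, vb)[0, 1])
    hits = 0
    for _ in range(n_permutations):
        r = np.corrcoef(va, rng.permutation(vb))[0, 1]
        if abs(r) >= r_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def merge_profiles(profiles: list[DatasetProfile], group_id: str) -> DatasetProfile:
    """Merge datasets into one group profile by summing counts and totals.

    RPM is recomputed against the summed library sizes (not averaged), which
    preserves the additive structure of the frequency formula.
    """
    if not profiles:
        raise ValidationError(f"group {group_id!r} has zero datasets")
    total = sum(p.total_reads for p in profiles)
    if total <= 0:
        raise ValidationError(f"group {group_id!r} has zero total reads")
    by_id: dict[str, ExoHit] = {}
    for p in profiles:
        for h in p.hits:
            if h.mirna_id in by_id:
                prev = by_id[h.mirna_id]
                by_id[h.mirna_id] = replace(prev, count=prev.count + h.count)
            else:
                by_id[h.mirna_id] = h
    hits = [
        replace(h, rpm=compute_rpm(h.count, total))
        for h in sorted(by_id.values(), key=lambda h: h.mirna_id)
    ]
    studies = sorted({p.metadata.study_id for p in profiles})
    hosts = sorted({p.metadata.host_species_code for p in profiles})
    sources = sorted({p.metadata.source_label for p in profiles})
    meta = DatasetMetadata(
        dataset_id=group_id,
        study_id="+".join(studies),
        source_label="+".join(sources),
        host_species_code="+".join(hosts),
    )
    return DatasetProfile(
        metadata=meta,
        hits=hits,
        total_reads=total,
        unassigned_reads=sum(p.unassigned_reads for p in profiles),
        unassigned_unique=sum(p.unassigned_unique for p in profiles),
    )


def compare_groups(
    profiles: list[DatasetProfile],
    grouping: dict[str, str],
    granularity: str = "id",
    keys: str = "union",
    transform: str = "log2p1",
) -> list[ComparisonResult]:
    """All pairwise comparisons between dataset groups.

    ``grouping`` maps dataset_id -> group name; profiles within a group are
    merged (summed counts, recomputed RPM).  A pair is ``intra_study`` iff
    the two groups share at least one study_id.  Results cover each
    unordered group pair once, in sorted group order.
    """
    by_group: dict[str, list[DatasetProfile]] = {}
    group_studies: dict[str, set[str]] = {}
    for p in profiles:
        gid = grouping.get(p.metadata.dataset_id)
        if gid is None:
            continue
        by_group.setdefault(gid, []).append(p)
        group_studies.setdefault(gid, set()).add(p.metadata.study_id)
    missing = set(grouping.values()) - set(by_group)
    if missing:
        raise ValidationError(f"groups with zero datasets: {sorted(missing)}")
    if len(by_group) < 2:
        raise ValidationError("compare_groups needs at least 2 groups")
    merged = {gid: merge_profiles(ps, gid) for gid, ps in by_group.items()}
    names = sorted(merged)
    results: list[ComparisonResult] = []
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            n_shared, n_union, pct = shared_fraction(
                merged[ga], merged[gb], granularity
            )
            r, p = profile_correlation(merged[ga], merged[gb], keys, transform)
            relation = (
                "intra_study"
                if group_studies[ga] & group_studies[gb]
                else "inter_study"
            )
            results.append(
                ComparisonResult((ga, gb), n_union, n_shared, pct, r, p, relation)
            )
    return results


def comparison_grid(results: list[ComparisonResult]) -> dict:
    """JSON-ready pairwise grid: r (with shared %) on the lower triangle,
    p-values on the upper triangle."""
    names = sorted({n for res in results for n in res.pair})
    grid = {"groups": names, "lower_r": {}, "lower_shared_pct": {}, "upper_p": {}}
    for res in results:
        a, b = sorted(res.pair)
        grid["lower_r"][f"{b}|{a}"] = res.r
        grid["lower_shared_pct"][f"{b}|{a}"] = res.shared_pct
        grid["upper_p"][f"{a}|{b}"] = res.p_value
    return grid
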