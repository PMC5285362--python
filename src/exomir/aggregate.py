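"""Cross-dataset aggregation: supporting numbers and the frequency matrix.

The frequency value of source species *i* and miRNA family *j* over datasets
``k = 1..n`` of a source group is

    F_ij = sum_k S_ijk / T_k * 1e9

where ``S_ijk`` is the read count attributed to (species i, family j) in
dataset k and ``T_k`` is that dataset's total library size.  The 1e9 scale
(RPM * 1000) is kept exactly as defined; for a single dataset every cell
reduces to ``rpm * 1000``.

The "supporting number" of a miRNA is the number of datasets (among those
considered) in which it was detected at all — the primary recurrence signal
used to separate sporadic hits from systematic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from exomir.errors import ValidationError
from exomir.exo_classify import DatasetProfile
from exomir.reference_io import Kingdom


@dataclass
class FrequencyMatrix:
    """Species (rows) x miRNA family (columns) matrix of frequency values."""

    values: pd.DataFrame  # index = species codes, columns = family keys
    n_datasets: int
    source_label: str = ""

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def families(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SupportEntry:
    supporting_number: int
    n_datasets_considered: int
    study_ids: frozenset[str]


@dataclass
class SupportTable:
    entries: dict[str, SupportEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, mirna_id: str) -> SupportEntry:
        return self.entries[mirna_id]

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self.entries


def _check_distinct_datasets(profiles: list[DatasetProfile]) -> None:
    ids = [p.metadata.dataset_id for p in profiles]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate dataset ids in profile list: {dupes}")


def supporting_numbers(
    profiles: list[DatasetProfile], min_count: int = 1
) -> SupportTable:
    """Per-miRNA presence counts across datasets.

    A miRNA is "present" in a dataset when its hit count is >= ``min_count``
    (default 1 read — no abundance threshold).  ``study_ids`` collects the
    distinct studies among the supporting datasets.
    """
    if not profiles:
        raise ValidationError("supporting_numbers needs at least one profile")
    _check_distinct_datasets(profiles)
    support: dict[str, int] = {}
    studies: dict[str, set[str]] = {}
    for p in profiles:
        for h in p.hits:
            if h.count >= min_count:
                support[h.mirna_id] = support.get(h.mirna_id, 0) + 1
                studies.setdefault(h.mirna_id, set()).add(p.metadata.study_id)
    n = len(profiles)
    return SupportTable(
        entries={
            mid: SupportEntry(cnt, n, frozenset(studies[mid]))
            for mid, cnt in support.items()
        }
    )


def frequency_matrix(
    profiles: list[DatasetProfile],
    source_label: str | None = None,
    dedup_shared: bool = False,
    other_kingdom_only: bool = False,
) -> FrequencyMatrix:
    """Build the species x family frequency matrix over a dataset group.

    ``source_label`` selects profiles by their metadata source (tissue/cell
    line); None takes all.  With ``dedup_shared`` a read sequence shared by
    m species contributes 1/m of its count to each (fractional attribution,
    for sensitivity analysis); the default credits every species fully.
    ``other_kingdom_only`` restricts to hits whose source kingdom differs
    from the host's, the view used for heatmap-style summaries.
    """
    selected = [
        p
        for p in profiles
        if source_label is None or p.metadata.source_label == source_label
    ]
    if not selected:
        raise ValidationError(f"no profiles selected (source_label={source_label!r})")
    _check_distinct_datasets(selected)
    cells: dict[tuple[str, str], float] = {}
    for p in selected:
        if p.total_reads <= 0:
            raise ValidationError(
                f"dataset {p.metadata.dataset_id}: total_reads must be > 0"
            )
        for h in p.hits:
            if other_kingdom_only and h.kingdom_class != "other_kingdom":
                continue
            weight = 1.0 / (1 + len(h.shared_with)) if dedup_shared else 1.0
            key = (h.species_code, h.family_key)
            cells[key] = cells.get(key, 0.0) + h.count * weight / p.total_reads * 1e9
    species = sorted({s for s, _ in cells})
    families = sorted({f for _, f in cells})
    values = pd.DataFrame(0.0, index=species, columns=families)
    for (s, f), v in cells.items():
        values.loc[s, f] = v
    return FrequencyMatrix(
        values=values,
        n_datasets=len(selected),
        source_label=source_label or "",
    )


def order_matrix(matrix: FrequencyMatrix, mode: str) -> FrequencyMatrix:
    """Reorder matrix axes: 'by_mirna' (family names), 'by_species'
    (species names), or 'by_frequency' (descending marginal sums, both axes)."""
    df = matrix.values
    if mode == "by_mirna":
        df = df.reindex(columns=sorted(df.columns))
    elif mode == "by_species":
        df = df.reindex(index=sorted(df.index))
    elif mode == "by_frequency":
        row_order = df.sum(axis=1).sort_values(ascending=False, kind="stable").index
        col_order = df.sum(axis=0).sort_values(ascending=False, kind="stable").index
        df = df.reindex(index=row_order, columns=col_order)
    else:
        raise ValueError(
            f"unknown ordering mode {mode!r}: expected by_mirna, by_species or by_frequency"
        )
    return FrequencyMatrix(
        values=df, n_datasets=matrix.n_datasets, source_label=matrix.source_label
    )


def top_exo_mirnas(support: SupportTable, n: int) -> list[tuple[str, int]]:
    """The n most frequently presented miRNAs, by supporting number descending;
    ties broken lexicographically by id (deterministic across runs)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(
        support.entries.items(), key=lambda kv: (-kv[1].supporting_number, kv[0])
    )
    return [(mid, e.supporting_number) for mid, e in ranked[:n]]


def kingdom_share(
    profiles: list[DatasetProfile],
    taxonomy,
    kingdom: Kingdom | str,
) -> dict[str, float]:
    """Of the distinct exo-miRNAs observed from one source kingdom, the
    percentage contributed by each source species.

    For virus-derived hits in B-cell datasets this answers "what share of
    the observed viral miRNAs come from EBV".  Returns an empty dict when no
    hit of that kingdom was observed.
    """
    kingdom = Kingdom(kingdom)
    by_species: dict[str, set[str]] = {}
    all_ids: set[str] = set()
    for p in profiles:
        for h in p.hits:
            if taxonomy.kingdom(h.species_code) != kingdom:
                continue
            by_species.setdefault(h.species_code, set()).add(h.mirna_id)
            all_ids.add(h.mirna_id)
    if not all_ids:
        return {}
    return {
        sp: 100.0 * len(ids) / len(all_ids) for sp, ids in sorted(by_species.items())
    }


def write_matrix_tsv(matrix: FrequencyMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="species")


def write_support_tsv(support: SupportTable, path) -> None:
    rows = [
        {
            "mirna_id": mid,
            "supporting_number": e.supporting_number,
            "n_datasets": e.n_datasets_considered,
            "n_studies": len(e.study_ids),
        }
        for mid, e in sorted(support.entries.items())
    ]
    pd.DataFrame(rows, columns=["mirna_id", "supporting_number", "n_datasets", "n_studies"]).to_csv(
        path, sep="\t", index=False
    )


def plot_matrix_heatmap(matrix: FrequencyMatrix, path) -> None:
    """Static heatmap export of a frequency matrix (log10(1+F) color scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * len(matrix.families)), max(3, 0.4 * len(matrix.species)))
    )
    data = np.log10(1.0 + matrix.values.to_numpy())
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(matrix.families)), matrix.families, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.species)), matrix.species, fontsize=6)
    ax.set_xlabel("miRNA family")
    ax.set_ylabel("source species")
    fig.colorbar(im, ax=ax, label="log10(1 + F)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
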