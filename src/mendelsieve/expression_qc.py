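"""qPCR delta-Ct normalization and coated-vs-hairless comparison.

ΔCt = Ct(target) − Ct(housekeeping reference); higher ΔCt means lower
relative expression.  Technical replicates are averaged (arithmetic mean of
Ct) before subtraction.  Two reference modes are provided: ``per_gene``
(one ΔCt per sample per housekeeping gene — the default, matching plots
that show per-housekeeping points) and ``mean`` (one ΔCt per sample against
the mean housekeeping Ct).

No hypothesis test is ever computed here; with the tiny group sizes this
analysis contract targets (e.g. five coated vs two hairless dogs), only
descriptive summaries are defensible, and a notice is emitted whenever a
phenotype group has fewer than three samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PHENOTYPES",
    "CtRecord",
    "DeltaCt",
    "SkippedSample",
    "DeltaCtResult",
    "PhenotypeSummary",
    "read_ct_table",
    "compute_delta_ct",
    "summarize_by_phenotype",
    "deltas_to_frame",
]

PHENOTYPES = ("coated", "hairless")

SMALL_GROUP_NOTICE = (
    "statistical testing not performed: fewer than 3 samples in group(s) {groups}; "
    "descriptive summaries only"
)


@dataclass(frozen=True)
class CtRecord:
    """One qPCR threshold-cycle measurement."""

    sample_id: str
    phenotype: str
    assay: str
    ct: float
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"Ct must be positive, got {self.ct}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"phenotype must be one of {PHENOTYPES}, got {self.phenotype!r}"
            )


@dataclass(frozen=True)
class DeltaCt:
    """Normalized expression value for one sample against one reference.

    ``housekeeping`` is the reference assay id, or ``"mean"`` when the ΔCt
    was taken against the mean housekeeping Ct.
    """

    sample_id: str
    phenotype: str
    target_assay: str
    housekeeping: str
    delta_ct: float


@dataclass(frozen=True)
class SkippedSample:
    sample_id: str
    reason: str


@dataclass(frozen=True)
class DeltaCtResult:
    deltas: tuple[DeltaCt, ...]
    skipped: tuple[SkippedSample, ...]


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Read the Ct CSV: sample_id, phenotype, assay, ct[, replicate]."""
    df = pd.read_csv(path)
    required = {"sample_id", "phenotype", "assay", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        rep = getattr(row, "replicate", None)
        rep = None if rep is None or pd.isna(rep) else int(rep)
        records.append(
            CtRecord(
                sample_id=str(row.sample_id),
                phenotype=str(row.phenotype),
                assay=str(row.assay),
                ct=float(row.ct),
                replicate=rep,
            )
        )
    return records


def _replicate_means(records: Iterable[CtRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "phenotype": r.phenotype,
                "assay": r.assay,
                "ct": r.ct,
            }
            for r in records
        ]
    )
    if df.empty:
        return df
    pheno = df.groupby("sample_id")["phenotype"].nunique()
    conflicted = pheno[pheno > 1].index.tolist()
    if conflicted:
        raise ValueError(f"conflicting phenotype labels for samples {conflicted}")
    return (
        df.groupby(["sample_id", "phenotype", "assay"], as_index=False)["ct"].mean()
    )


def compute_delta_ct(
    records: Sequence[CtRecord],
    target: str,
    housekeeping: Sequence[str],
    reference_mode: str = "per_gene",
) -> DeltaCtResult:
    """ΔCt per sample: target Ct minus housekeeping reference Ct.

    Replicates are averaged first.  Samples lacking the target assay or any
    housekeeping assay are reported in ``skipped`` rather than silently
    dropped.
    """
    if reference_mode not in {"per_gene", "mean"}:
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    if not housekeeping:
        raise ValueError("at least one housekeeping assay is required")
    means = _replicate_means(records)
    deltas: list[DeltaCt] = []
    skipped: list[SkippedSample] = []
    if means.empty:
        return DeltaCtResult((), ())
    for sample_id, sub in means.groupby("sample_id", sort=True):
        cts = dict(zip(sub["assay"], sub["ct"]))
        phenotype = sub["phenotype"].iloc[0]
        if target not in cts:
            skipped.append(SkippedSample(str(sample_id), f"no {target} measurement"))
            continue
        missing_hk = [h for h in housekeeping if h not in cts]
        if missing_hk:
            skipped.append(
                SkippedSample(
                    str(sample_id), f"missing housekeeping assay(s) {missing_hk}"
                )
            )
            continue
        if reference_mode == "per_gene":
            for hk in housekeeping:
                deltas.append(
                    DeltaCt(str(sample_id), phenotype, target, hk, cts[target] - cts[hk])
                )
        else:
            hk_mean = sum(cts[h] for h in housekeeping) / len(housekeeping)
            deltas.append(
                DeltaCt(str(sample_id), phenotype, target, "mean", cts[target] - hk_mean)
            )
    return DeltaCtResult(tuple(deltas), tuple(skipped))


def deltas_to_frame(deltas: Iterable[DeltaCt]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "phenotype": d.phenotype,
                "target_assay": d.target_assay,
                "housekeeping": d.housekeeping,
                "delta_ct": d.delta_ct,
            }
            for d in deltas
        ],
        columns=["sample_id", "phenotype", "target_assay", "housekeeping", "delta_ct"],
    )


@dataclass(frozen=True)
class PhenotypeSummary:
    """Descriptive per-phenotype summary plus the small-group notice."""

    table: pd.DataFrame
    notice: str | None


def summarize_by_phenotype(deltas: Sequence[DeltaCt]) -> PhenotypeSummary:
    """Per-phenotype, per-reference descriptive summary (n, mean, min, max).

    ``n`` counts distinct samples.  When any phenotype group has fewer than
    three samples a notice is attached; no hypothesis test is computed in
    any case.
    """
    df = deltas_to_frame(deltas)
    if df.empty:
        return PhenotypeSummary(
            pd.DataFrame(
                columns=["phenotype", "housekeeping", "n", "mean", "min", "max"]
            ),
            SMALL_GROUP_NOTICE.format(groups="all (no data)"),
        )
    summary = (
        df.groupby(["phenotype", "housekeeping"], as_index=False)
        .agg(
            n=("sample_id", "nunique"),
            mean=("delta_ct", "mean"),
            min=("delta_ct", "min"),
            max=("delta_ct", "max"),
        )
        .sort_values(["phenotype", "housekeeping"])
        .reset_index(drop=True)
    )
    group_n = df.groupby("phenotype")["sample_id"].nunique()
    small = [p for p in PHENOTYPES if group_n.get(p, 0) < 3]
    notice = SMALL_GROUP_NOTICE.format(groups=", ".join(small)) if small else None
    return PhenotypeSummary(summary, notice)
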