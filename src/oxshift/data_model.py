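"""Typed data model and CSV readers/writers shared by every pipeline stage.

Conventions
-----------
- Sample identifiers serialize as ``condition.time.replicate`` (e.g.
  ``O2.15.r2``): human-diffable and sortable.
- Times are integer minutes on a fixed grid; no date-time arithmetic.
- Missing values are the literal token ``NA`` in every CSV dialect and
  ``numpy.nan`` in memory.
- Feature tables are wide CSVs: first column ``feature_id``, then one
  column per sample per channel with header ``sample_id:channel``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ASSAYS = (
    "metabolomics_intra",
    "metabolomics_extra",
    "proteomics",
    "transcriptomics",
)

#: channels carried by a metabolomics feature table
METAB_CHANNELS = ("parent_12C", "reference_13C")

NA_TOKEN = "NA"


class DesignError(ValueError):
    """A study design violates a structural invariant."""


class FormatError(ValueError):
    """A feature table cannot be reconciled with its design."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one physical sample.

    ``od600`` is required (strictly positive) for intracellular assays,
    where it normalizes signal per cell density; ``dilution_factor`` is
    the fold dilution applied before measurement (>= 1).
    """

    condition: str
    time_min: int
    replicate: str
    od600: float | None = None
    batch: str = "b1"
    dilution_factor: float = 1.0
    compartment: str = "intracellular"

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise DesignError(f"negative time {self.time_min} for {self.sample_id}")
        if self.dilution_factor < 1:
            raise DesignError(
                f"dilution_factor {self.dilution_factor} < 1 for {self.sample_id}"
            )
        if self.compartment == "intracellular":
            if self.od600 is None or not self.od600 > 0:
                raise DesignError(
                    f"intracellular sample {self.sample_id} requires od600 > 0"
                )

    @property
    def sample_id(self) -> str:
        return f"{self.condition}.{self.time_min}.{self.replicate}"


@dataclass
class StudyDesign:
    """The sampling scheme of a two-arm time-course study.

    ``sampling`` maps (condition, time_min, replicate, assay) tuples to
    :class:`SampleMeta`; a tuple's presence means the sample exists.
    """

    conditions: list[str]
    timepoints_min: list[int]
    replicates: dict[str, list[str]]
    sampling: dict[tuple[str, int, str, str], SampleMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if sorted(set(self.timepoints_min)) != list(self.timepoints_min):
            raise DesignError(
                f"timepoints must be strictly increasing, got {self.timepoints_min}"
            )
        if 0 not in self.timepoints_min:
            raise DesignError("design lacks time 0")
        seen_t0 = {c: False for c in self.conditions}
        for (cond, t, _rep, assay) in self.sampling:
            if assay not in ASSAYS:
                raise DesignError(f"unknown assay {assay!r}")
            if cond not in self.conditions:
                raise DesignError(f"sample condition {cond!r} not in design conditions")
            if t not in self.timepoints_min:
                raise DesignError(f"sample time {t} not on the design grid")
            if t == 0:
                seen_t0[cond] = True
        missing = [c for c, ok in seen_t0.items() if not ok]
        if missing:
            raise DesignError(
                f"missing time 0 sample(s) for condition(s): {', '.join(missing)}"
            )

    def samples(self, assay: str, condition: str | None = None) -> list[SampleMeta]:
        """Samples of one assay, ordered by (condition, time, replicate)."""
        out = [
            m
            for (c, _t, _r, a), m in self.sampling.items()
            if a == assay and (condition is None or c == condition)
        ]
        return sorted(out, key=lambda m: (m.condition, m.time_min, m.replicate))


@dataclass
class FeatureTable:
    """A feature x sample intensity/abundance matrix with channel labels.

    ``values`` is indexed by ``feature_id`` with a two-level column index
    (sample_id, channel). Metabolomics tables carry both a ``parent_12C``
    and a ``reference_13C`` channel for every sample; transcript and
    protein tables carry a single ``abundance`` channel. Raw intensities
    are non-negative; log2 LFQ protein values may be any real.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    assay: str

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature identifiers: {dups}")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample/channel columns")
        if self.assay.startswith("metabolomics"):
            for meta in self.samples:
                for ch in METAB_CHANNELS:
                    if (meta.sample_id, ch) not in self.values.columns:
                        raise FormatError(
                            f"sample {meta.sample_id} lacks channel {ch}"
                        )
            bad = self.values.lt(0).any()
            if bad.any():
                cols = [f"{s}:{c}" for (s, c) in self.values.columns[bad]]
                raise FormatError(f"negative raw intensity in column(s): {cols}")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def channel(self, channel: str) -> pd.DataFrame:
        """Feature x sample matrix for one channel (columns are sample ids)."""
        sub = self.values.xs(channel, axis=1, level=1)
        return sub

    def sample_meta(self, sample_id: str) -> SampleMeta:
        for m in self.samples:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)


@dataclass
class NormalizedSeries:
    """Per-feature, per-condition log2 fold changes versus baseline.

    ``per_replicate_log2fc`` maps (time, replicate) -> log2FC (NaN when
    missing); ``mean_log2fc`` is the arithmetic mean over the available
    per-replicate log2 values at each time; ``n_used`` counts them.
    """

    feature: str
    condition: str
    per_replicate_log2fc: dict[tuple[int, str], float]
    mean_log2fc: dict[int, float]
    n_used: dict[int, int]

    def max_abs_log2fc(self) -> float:
        """Largest |mean log2FC| over non-missing time points (NaN if none)."""
        vals = [v for v in self.mean_log2fc.values() if np.isfinite(v)]
        if not vals:
            return float("nan")
        return float(max(abs(v) for v in vals))


@dataclass(frozen=True)
class SignificanceThresholds:
    """Dual significance rule: linear |fold change| and BH FDR cutoffs.

    The comparisons are strict, as printed in figure legends
    (|fold change| > threshold; FDR < threshold).
    """

    min_abs_fold_change: float = 1.5
    max_fdr: float = 0.01

    def __post_init__(self) -> None:
        if not self.min_abs_fold_change > 1:
            raise ValueError("min_abs_fold_change must exceed 1")
        if not 0 < self.max_fdr < 1:
            raise ValueError("max_fdr must lie in (0, 1)")


# ---------------------------------------------------------------------------
# readers


DESIGN_COLUMNS = [
    "condition",
    "time_min",
    "replicate",
    "assay",
    "od600",
    "batch",
    "dilution_factor",
    "compartment",
]


def load_design(path: str | Path) -> StudyDesign:
    """Read a ``design.csv`` and return a validated :class:`StudyDesign`.

    Raises :class:`DesignError` naming the offending condition or sample
    when an invariant is violated (missing t=0, duplicate sample tuple).
    """
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)
    missing_cols = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"design file lacks column(s): {missing_cols}")
    sampling: dict[tuple[str, int, str, str], SampleMeta] = {}
    for _, row in df.iterrows():
        key = (
            str(row["condition"]),
            int(row["time_min"]),
            str(row["replicate"]),
            str(row["assay"]),
        )
        if key in sampling:
            raise DesignError(f"duplicate sample tuple {key}")
        od = None if pd.isna(row["od600"]) else float(row["od600"])
        sampling[key] = SampleMeta(
            condition=key[0],
            time_min=key[1],
            replicate=key[2],
            od600=od,
            batch=str(row["batch"]),
            dilution_factor=float(row["dilution_factor"]),
            compartment=str(row["compartment"]),
        )
    conditions = sorted({k[0] for k in sampling})
    timepoints = sorted({k[1] for k in sampling})
    replicates = {
        c: sorted({k[2] for k in sampling if k[0] == c}) for c in conditions
    }
    return StudyDesign(
        conditions=conditions,
        timepoints_min=timepoints,
        replicates=replicates,
        sampling=sampling,
    )


def design_to_frame(design: StudyDesign) -> pd.DataFrame:
    rows = []
    for (cond, t, rep, assay), m in sorted(design.sampling.items()):
        rows.append(
            {
                "condition": cond,
                "time_min": t,
                "replicate": rep,
                "assay": assay,
                "od600": m.od600,
                "batch": m.batch,
                "dilution_factor": m.dilution_factor,
                "compartment": m.compartment,
            }
        )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def load_feature_table(
    path: str | Path, design: StudyDesign, assay: str
) -> FeatureTable:
    """Read a wide ``features.csv`` and join sample metadata from the design.

    Column headers must be ``sample_id:channel`` and resolve to sample
    tuples present in the design for ``assay``; unresolvable columns are
    rejected. Empty cells / ``NA`` become NaN and stay NaN downstream.
    """
    df = pd.read_csv(
        path, index_col=0, na_values=[NA_TOKEN, ""], keep_default_na=False
    )
    known = {m.sample_id: m for m in design.samples(assay)}
    columns: list[tuple[str, str]] = []
    metas: dict[str, SampleMeta] = {}
    for col in df.columns:
        if ":" not in col:
            raise FormatError(f"column {col!r} is not of the form sample_id:channel")
        sid, channel = col.rsplit(":", 1)
        if sid not in known:
            raise FormatError(
                f"column {col!r} names sample {sid!r} absent from the design "
                f"for assay {assay!r}"
            )
        columns.append((sid, channel))
        metas[sid] = known[sid]
    out = df.copy()
    out.columns = pd.MultiIndex.from_tuples(columns, names=["sample", "channel"])
    out = out.astype(float)
    samples = sorted(metas.values(), key=lambda m: (m.condition, m.time_min, m.replicate))
    return FeatureTable(values=out, samples=samples, assay=assay)


def feature_table_to_frame(table: FeatureTable) -> pd.DataFrame:
    """Flatten a FeatureTable back to its on-disk wide layout."""
    df = table.values.copy()
    df.columns = [f"{s}:{c}" for (s, c) in df.columns]
    df.index.name = "feature_id"
    return df


# ---------------------------------------------------------------------------
# writer

#: >= 10 significant digits so re-reading reproduces reals to printed precision
FLOAT_FORMAT = "%.12g"


def write_results(
    tables: Mapping[str, pd.DataFrame], path: str | Path
) -> dict[str, dict]:
    """Write named result tables as CSVs plus a JSON sidecar manifest.

    Rows are sorted by the index (feature identifier) and columns kept in
    the given order, so two writes of the same input are byte-identical.
    Returns the manifest: file name -> {rows, sha256}.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for name, df in tables.items():
        fname = f"{name}.csv"
        fpath = outdir / fname
        out = df.sort_index()
        text = out.to_csv(float_format=FLOAT_FORMAT, na_rep=NA_TOKEN, lineterminator="\n")
        fpath.write_text(text)
        manifest[fname] = {
            "rows": int(len(out)),
            "sha256": hashlib.sha256(text.encode()).hexdigest(),
        }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def normalized_series_to_frames(
    series: Iterable[NormalizedSeries],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format frames (per-replicate, per-time-mean) for a series set."""
    rep_rows, mean_rows = [], []
    for s in series:
        for (t, rep), v in sorted(s.per_replicate_log2fc.items()):
            rep_rows.append(
                {
                    "feature": s.feature,
                    "condition": s.condition,
                    "time_min": t,
                    "replicate": rep,
                    "log2fc": v,
                }
            )
        for t in sorted(s.mean_log2fc):
            mean_rows.append(
                {
                    "feature": s.feature,
                    "condition": s.condition,
                    "time_min": t,
                    "mean_log2fc": s.mean_log2fc[t],
                    "n_used": s.n_used[t],
                }
            )
    rep = pd.DataFrame(
        rep_rows, columns=["feature", "condition", "time_min", "replicate", "log2fc"]
    ).set_index("feature")
    mean = pd.DataFrame(
        mean_rows, columns=["feature", "condition", "time_min", "mean_log2fc", "n_used"]
    ).set_index("feature")
    return rep, mean
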