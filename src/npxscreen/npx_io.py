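"""Reading, validation and writing of NPX long-format tables.

The internal currency of the whole pipeline is :class:`NPXMatrix`, a dense
proteins-by-samples matrix of NPX values (Olink's relative abundance unit,
already on a log2 scale) together with a missing-value mask and typed
protein/sample annotations.  Input files are plain CSV or TSV: one long NPX
table (one row per sample x assay measurement) and one sample-annotation
table carrying the trial structure (subject, arm, timepoint) and optional
clinical covariates (sex, age, NIHSS, ESRS).

No imputation happens anywhere downstream: contrasts operate on per-protein
complete observations (complete pairs for paired contrasts), so cells absent
from the input simply stay masked.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Arm",
    "Timepoint",
    "Sex",
    "ProteinAssay",
    "SampleRecord",
    "NPXMatrix",
    "StudyDesign",
    "read_npx_long",
    "write_npx_long",
    "validate_design",
    "matrix_from_frames",
]


class Arm(str, enum.Enum):
    TREATMENT = "treatment"
    CONTROL = "control"


class Timepoint(str, enum.Enum):
    BASELINE = "baseline"
    POST = "post"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


#: Accepted spellings for the arm column, lower-cased.
ARM_ALIASES: Mapping[str, Arm] = {
    "treatment": Arm.TREATMENT,
    "treat": Arm.TREATMENT,
    "t": Arm.TREATMENT,
    "intervention": Arm.TREATMENT,
    "ipc": Arm.TREATMENT,
    "control": Arm.CONTROL,
    "ctrl": Arm.CONTROL,
    "c": Arm.CONTROL,
}

#: Accepted spellings for the timepoint column, lower-cased.
TIMEPOINT_ALIASES: Mapping[str, Timepoint] = {
    "baseline": Timepoint.BASELINE,
    "pre": Timepoint.BASELINE,
    "t1": Timepoint.BASELINE,
    "c1": Timepoint.BASELINE,
    "1": Timepoint.BASELINE,
    "v1": Timepoint.BASELINE,
    "post": Timepoint.POST,
    "t2": Timepoint.POST,
    "c2": Timepoint.POST,
    "2": Timepoint.POST,
    "v2": Timepoint.POST,
    "followup": Timepoint.POST,
    "follow-up": Timepoint.POST,
}

SEX_ALIASES: Mapping[str, Sex] = {
    "male": Sex.MALE,
    "m": Sex.MALE,
    "female": Sex.FEMALE,
    "f": Sex.FEMALE,
    "unknown": Sex.UNKNOWN,
    "": Sex.UNKNOWN,
    "na": Sex.UNKNOWN,
}

#: Case-insensitive header aliases for the NPX long table.
NPX_COLUMN_ALIASES: Mapping[str, str] = {
    "sample_id": "sample_id",
    "sampleid": "sample_id",
    "sample": "sample_id",
    "assay_id": "assay_id",
    "assay": "assay_id",
    "olinkid": "assay_id",
    "protein": "assay_id",
    "npx": "npx",
    "npx_value": "npx",
    "value": "npx",
    "gene_symbol": "gene_symbol",
    "gene": "gene_symbol",
    "uniprot": "uniprot_id",
    "uniprot_id": "uniprot_id",
    "panel": "panel_name",
    "panel_name": "panel_name",
    "lod": "lod",
    "qc_warning": "qc_warning",
    "qc": "qc_warning",
}

#: Case-insensitive header aliases for the sample-annotation table.
ANNOTATION_COLUMN_ALIASES: Mapping[str, str] = {
    "sample_id": "sample_id",
    "sampleid": "sample_id",
    "sample": "sample_id",
    "subject_id": "subject_id",
    "subjectid": "subject_id",
    "subject": "subject_id",
    "patient": "subject_id",
    "arm": "arm",
    "group": "arm",
    "timepoint": "timepoint",
    "time": "timepoint",
    "visit": "timepoint",
    "sex": "sex",
    "gender": "sex",
    "age": "age",
    "nihss": "nihss",
    "esrs": "esrs",
    "essen": "esrs",
}

_MISSING_NPX = {"", "na", "nan", "none", "null"}

NIHSS_RANGE = (0, 42)
ESRS_RANGE = (0, 9)


@dataclass(frozen=True)
class ProteinAssay:
    """One assay on the panel, keyed by its unique assay id."""

    assay_id: str
    gene_symbol: str = ""
    uniprot_id: str | None = None
    panel_name: str | None = None

    def __post_init__(self) -> None:
        if not self.assay_id:
            raise ValueError("assay_id must be non-empty")
        if not self.gene_symbol:
            # the panel's assay id doubles as the gene symbol when none given
            object.__setattr__(self, "gene_symbol", self.assay_id)


@dataclass(frozen=True)
class SampleRecord:
    """One sample with its trial annotations and clinical scores."""

    sample_id: str
    subject_id: str
    arm: Arm
    timepoint: Timepoint
    sex: Sex = Sex.UNKNOWN
    age: float | None = None
    nihss: int | None = None
    esrs: int | None = None

    def __post_init__(self) -> None:
        if self.nihss is not None and not (NIHSS_RANGE[0] <= self.nihss <= NIHSS_RANGE[1]):
            raise ValueError(
                f"sample {self.sample_id!r}: NIHSS {self.nihss} outside {NIHSS_RANGE}"
            )
        if self.esrs is not None and not (ESRS_RANGE[0] <= self.esrs <= ESRS_RANGE[1]):
            raise ValueError(
                f"sample {self.sample_id!r}: ESRS {self.esrs} outside {ESRS_RANGE}"
            )


@dataclass
class NPXMatrix:
    """Dense proteins x samples NPX matrix with a missing mask.

    ``values[i, j]`` is the NPX of protein ``proteins[i]`` in sample
    ``samples[j]``; masked cells hold NaN and ``missing_mask[i, j]`` is True.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    proteins: list[ProteinAssay]
    samples: list[SampleRecord]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if self.values.shape != (len(self.proteins), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.proteins)} proteins x {len(self.samples)} samples"
            )
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-missing NPX values must be finite")

    @property
    def protein_ids(self) -> list[str]:
        return [p.assay_id for p in self.proteins]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def protein_index(self, assay_id: str) -> int:
        try:
            return self.protein_ids.index(assay_id)
        except ValueError:
            raise KeyError(f"protein {assay_id!r} not on the panel") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in the matrix") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "NPXMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return NPXMatrix(
            values=self.values[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
            proteins=list(self.proteins),
            samples=[self.samples[i] for i in idx],
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format frame of the observed (non-missing) cells."""
        rows = []
        for i, prot in enumerate(self.proteins):
            for j, samp in enumerate(self.samples):
                if not self.missing_mask[i, j]:
                    rows.append((samp.sample_id, prot.assay_id, self.values[i, j]))
        return pd.DataFrame(rows, columns=["sample_id", "assay_id", "npx"])


@dataclass
class StudyDesign:
    """Partition of samples into the four trial cells with pairing info.

    ``groups`` maps the four cell labels T1 (treatment baseline),
    T2 (treatment post), C1 (control baseline), C2 (control post) to sample-id
    lists.  ``paired_subjects`` lists, per arm, the subjects contributing a
    sample to both of the arm's timepoints; these drive the paired contrasts.
    """

    groups: dict[str, list[str]]
    paired_subjects: dict[Arm, list[str]]
    unpaired_subjects: list[str] = field(default_factory=list)
    sample_by_id: dict[str, SampleRecord] = field(default_factory=dict)
    subject_samples: dict[str, dict[Timepoint, str]] = field(default_factory=dict)

    GROUP_LABELS = ("T1", "T2", "C1", "C2")

    def group_samples(self, label: str) -> list[str]:
        if label not in self.groups:
            raise KeyError(f"unknown group {label!r}; expected one of {self.GROUP_LABELS}")
        return self.groups[label]

    def paired_sample_ids(self, arm: Arm) -> list[tuple[str, str]]:
        """(baseline_sample, post_sample) per paired subject of an arm."""
        out = []
        for subj in self.paired_subjects[arm]:
            tp = self.subject_samples[subj]
            out.append((tp[Timepoint.BASELINE], tp[Timepoint.POST]))
        return out


# ---------------------------------------------------------------------------
# reading


def _sniff_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _canonical_columns(df: pd.DataFrame, aliases: Mapping[str, str], path: Path) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in aliases:
            canon = aliases[key]
            if canon in mapping.values():
                raise ValueError(f"{path}: two columns both map to {canon!r}")
            mapping[col] = canon
    return df.rename(columns=mapping)


def _read_table(path: Path, aliases: Mapping[str, str]) -> pd.DataFrame:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return _canonical_columns(df, aliases, path)


def _parse_enum(raw: str, aliases: Mapping[str, object], what: str, sample_id: str):
    key = str(raw).strip().lower()
    if key not in aliases:
        accepted = sorted(set(aliases))
        raise ValueError(
            f"sample {sample_id!r}: cannot parse {what} label {raw!r}; "
            f"accepted spellings: {accepted}"
        )
    return aliases[key]


def _opt_int(raw: str) -> int | None:
    raw = str(raw).strip()
    if raw.lower() in _MISSING_NPX:
        return None
    return int(round(float(raw)))


def _opt_float(raw: str) -> float | None:
    raw = str(raw).strip()
    if raw.lower() in _MISSING_NPX:
        return None
    return float(raw)


def parse_annotation_frame(ann: pd.DataFrame) -> list[SampleRecord]:
    """Build :class:`SampleRecord` objects from a canonicalised annotation frame."""
    required = {"sample_id", "subject_id", "arm", "timepoint"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table lacks required columns: {sorted(missing)}")
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for _, row in ann.iterrows():
        sid = str(row["sample_id"]).strip()
        if sid in seen:
            raise ValueError(f"duplicate sample_id {sid!r} in annotations")
        seen.add(sid)
        records.append(
            SampleRecord(
                sample_id=sid,
                subject_id=str(row["subject_id"]).strip(),
                arm=_parse_enum(row["arm"], ARM_ALIASES, "arm", sid),
                timepoint=_parse_enum(row["timepoint"], TIMEPOINT_ALIASES, "timepoint", sid),
                sex=_parse_enum(row["sex"], SEX_ALIASES, "sex", sid) if "sex" in ann.columns else Sex.UNKNOWN,
                age=_opt_float(row["age"]) if "age" in ann.columns else None,
                nihss=_opt_int(row["nihss"]) if "nihss" in ann.columns else None,
                esrs=_opt_int(row["esrs"]) if "esrs" in ann.columns else None,
            )
        )
    return records


def matrix_from_frames(npx: pd.DataFrame, samples: list[SampleRecord]) -> NPXMatrix:
    """Pivot a canonicalised long NPX frame onto annotated samples.

    The matrix covers the Cartesian product of observed assays x annotated
    samples; cells with no row in the frame are masked as missing.
    """
    required = {"sample_id", "assay_id", "npx"}
    missing = required - set(npx.columns)
    if missing:
        raise ValueError(f"NPX table lacks required columns: {sorted(missing)}")

    dup = npx.duplicated(subset=["sample_id", "assay_id"], keep=False)
    if dup.any():
        first = npx.loc[dup, ["sample_id", "assay_id"]].iloc[0]
        raise ValueError(
            f"duplicate NPX rows for (sample_id={first['sample_id']!r}, "
            f"assay_id={first['assay_id']!r})"
        )

    annotated = {s.sample_id for s in samples}
    unknown = set(npx["sample_id"].astype(str)) - annotated
    if unknown:
        raise ValueError(
            f"samples present in NPX table but absent from annotations: {sorted(unknown)}"
        )

    assay_meta: dict[str, ProteinAssay] = {}
    for _, row in npx.iterrows():
        aid = str(row["assay_id"]).strip()
        if aid not in assay_meta:
            assay_meta[aid] = ProteinAssay(
                assay_id=aid,
                gene_symbol=str(row.get("gene_symbol", "") or "").strip() or aid,
                uniprot_id=str(row["uniprot_id"]).strip() or None if "uniprot_id" in npx.columns else None,
                panel_name=str(row["panel_name"]).strip() or None if "panel_name" in npx.columns else None,
            )
    proteins = [assay_meta[a] for a in sorted(assay_meta)]
    p_index = {p.assay_id: i for i, p in enumerate(proteins)}
    s_index = {s.sample_id: j for j, s in enumerate(samples)}

    values = np.full((len(proteins), len(samples)), np.nan)
    mask = np.ones_like(values, dtype=bool)
    for _, row in npx.iterrows():
        raw = str(row["npx"]).strip()
        i = p_index[str(row["assay_id"]).strip()]
        j = s_index[str(row["sample_id"]).strip()]
        if raw.lower() in _MISSING_NPX:
            continue  # explicit NA row stays masked
        values[i, j] = float(raw)
        mask[i, j] = False
    return NPXMatrix(values=values, missing_mask=mask, proteins=proteins, samples=list(samples))


def read_npx_long(npx_path: str | Path, annotation_path: str | Path) -> NPXMatrix:
    """Read an NPX long-format table plus sample annotations into a matrix.

    Both files may be CSV or TSV (auto-detected from the header line); header
    names are matched case-insensitively against the documented alias tables.
    """
    npx_path, annotation_path = Path(npx_path), Path(annotation_path)
    for p in (npx_path, annotation_path):
        if not p.exists():
            raise FileNotFoundError(p)
    npx = _read_table(npx_path, NPX_COLUMN_ALIASES)
    ann = _read_table(annotation_path, ANNOTATION_COLUMN_ALIASES)
    samples = parse_annotation_frame(ann)
    return matrix_from_frames(npx, samples)


# ---------------------------------------------------------------------------
# writing


def write_npx_long(matrix: NPXMatrix, npx_path: str | Path, annotation_path: str | Path) -> None:
    """Write a matrix back to the long NPX + annotation file pair (TSV)."""
    long = matrix.to_long_frame()
    gene = {p.assay_id: p.gene_symbol for p in matrix.proteins}
    long["gene_symbol"] = long["assay_id"].map(gene)
    long.to_csv(npx_path, sep="\t", index=False)

    rows = []
    for s in matrix.samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "subject_id": s.subject_id,
                "arm": s.arm.value,
                "timepoint": s.timepoint.value,
                "sex": s.sex.value,
                "age": "" if s.age is None else s.age,
                "nihss": "" if s.nihss is None else s.nihss,
                "esrs": "" if s.esrs is None else s.esrs,
            }
        )
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table in the pipeline's standard TSV dialect."""
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# design validation


def validate_design(matrix: NPXMatrix) -> StudyDesign:
    """Partition annotated samples into the four trial cells T1/T2/C1/C2.

    Subjects contributing both of their arm's timepoints are paired; subjects
    lacking one timepoint go on the unpaired list and are excluded from
    paired contrasts only.  A subject annotated with two different arms, or
    an empty trial cell, is a hard error.
    """
    arm_of: dict[str, Arm] = {}
    subject_samples: dict[str, dict[Timepoint, str]] = {}
    for s in matrix.samples:
        prev = arm_of.get(s.subject_id)
        if prev is not None and prev is not s.arm:
            raise ValueError(
                f"subject {s.subject_id!r} annotated in both arms ({prev.value} and {s.arm.value})"
            )
        arm_of[s.subject_id] = s.arm
        tp = subject_samples.setdefault(s.subject_id, {})
        if s.timepoint in tp:
            raise ValueError(
                f"subject {s.subject_id!r} has two samples at timepoint {s.timepoint.value}"
            )
        tp[s.timepoint] = s.sample_id

    label = {
        (Arm.TREATMENT, Timepoint.BASELINE): "T1",
        (Arm.TREATMENT, Timepoint.POST): "T2",
        (Arm.CONTROL, Timepoint.BASELINE): "C1",
        (Arm.CONTROL, Timepoint.POST): "C2",
    }
    groups: dict[str, list[str]] = {g: [] for g in StudyDesign.GROUP_LABELS}
    for s in matrix.samples:
        groups[label[(s.arm, s.timepoint)]].append(s.sample_id)

    empty = [g for g, ids in groups.items() if not ids]
    if empty:
        raise ValueError(f"empty study group(s): {empty}")

    paired: dict[Arm, list[str]] = {Arm.TREATMENT: [], Arm.CONTROL: []}
    unpaired: list[str] = []
    for subj in sorted(subject_samples):
        tp = subject_samples[subj]
        if Timepoint.BASELINE in tp and Timepoint.POST in tp:
            paired[arm_of[subj]].append(subj)
        else:
            unpaired.append(subj)

    return StudyDesign(
        groups=groups,
        paired_subjects=paired,
        unpaired_subjects=unpaired,
        sample_by_id={s.sample_id: s for s in matrix.samples},
        subject_samples=subject_samples,
    )
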