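"""Domain types and readers/writers for abundance tables, metadata and alignments.

The in-memory containers mirror the products of standard shotgun-metagenomics
profiling: a per-cohort species-by-sample relative-abundance matrix
(MetaPhlAn-style merged table), per-sample clinical metadata, marker-gene
multiple sequence alignments (StrainPhlAn-style aligned FASTA) and named
feature-identifier sets (signatures).

Abundances are stored as fractions in [0, 1].  Merged profiler tables are
commonly expressed as percentages; the reader auto-detects that convention
(any sample column summing above 1.5) and rescales by 1/100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

MSA_ALPHABET = frozenset("ACGT-N")


class CrcMetaError(Exception):
    """Base class for crcmeta errors."""


class ParseError(CrcMetaError):
    pass


class ValidationError(CrcMetaError):
    pass


class AlignmentError(CrcMetaError):
    pass


class Condition(str, Enum):
    CONTROL = "control"
    ADENOMA = "adenoma"
    CRC = "CRC"


class Stage(str, Enum):
    S0 = "0"
    SI = "I"
    SII = "II"
    SIII = "III"
    SIV = "IV"
    UNKNOWN = "unknown"


class Location(str, Enum):
    RIGHT = "right"
    LEFT = "left"
    UNKNOWN = "unknown"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    MISSING = "missing"


#: stages considered early ("0"-"II") vs late ("III"-"IV") disease
EARLY_STAGES = (Stage.S0, Stage.SI, Stage.SII)
LATE_STAGES = (Stage.SIII, Stage.SIV)


@dataclass
class CohortProfile:
    """One cohort's feature-by-sample relative-abundance matrix.

    abundances[i, j] is the relative abundance (fraction of the community) of
    feature ``feature_ids[i]`` in sample ``sample_ids[j]``.
    """

    cohort_id: str
    feature_ids: list[str]
    sample_ids: list[str]
    abundances: np.ndarray  # shape (n_features, n_samples)

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"abundance matrix shape {self.abundances.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dups = _duplicates(self.feature_ids)
            raise ValidationError(f"duplicate feature ids: {sorted(dups)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dups = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample ids: {sorted(dups)[:5]}")
        if self.abundances.size:
            if np.any(~np.isfinite(self.abundances)):
                raise ValidationError("non-finite abundance values")
            if self.abundances.min() < 0 or self.abundances.max() > 1:
                raise ValidationError("abundance values outside [0, 1]")
            colsums = self.abundances.sum(axis=0)
            if np.any(colsums > 1 + 1e-6):
                bad = [self.sample_ids[j] for j in np.where(colsums > 1 + 1e-6)[0]]
                raise ValidationError(f"sample column sums exceed 1: {bad[:5]}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundances, index=self.feature_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CohortProfile":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return CohortProfile(
            cohort_id=self.cohort_id,
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_ids),
            abundances=self.abundances[:, cols],
        )


@dataclass
class SampleMetadata:
    """Per-sample clinical covariates and class labels.

    Stage and primary-tumor location are only defined for CRC samples; for
    anything else they must carry the ``unknown`` sentinel.  Missing age/BMI
    are NaN, missing sex is :attr:`Sex.MISSING` — never imputed at this layer.
    """

    sample_id: str
    cohort_id: str
    condition: Condition
    stage: Stage = Stage.UNKNOWN
    location: Location = Location.UNKNOWN
    age: float = float("nan")
    sex: Sex = Sex.MISSING
    bmi: float = float("nan")
    primary_tumor_in_situ: str = "not_applicable"  # {yes, no, not_applicable}

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        if not isinstance(self.stage, Stage):
            self.stage = Stage(str(self.stage))
        self.location = Location(self.location)
        self.sex = Sex(self.sex)
        if self.stage is not Stage.UNKNOWN and self.condition is not Condition.CRC:
            raise ValidationError(
                f"sample {self.sample_id}: stage given for non-CRC condition"
            )
        if self.location is not Location.UNKNOWN and self.condition is not Condition.CRC:
            raise ValidationError(
                f"sample {self.sample_id}: tumor location given for non-CRC condition"
            )
        if self.primary_tumor_in_situ not in ("yes", "no", "not_applicable"):
            raise ValidationError(
                f"sample {self.sample_id}: bad primary_tumor_in_situ value"
            )


@dataclass
class MsaSet:
    """A marker-gene multiple sequence alignment for one SGB."""

    sgb_id: str
    sample_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        bad = set("".join(self.sequences)) - MSA_ALPHABET
        if bad:
            raise AlignmentError(f"symbols outside alphabet: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_array(self) -> np.ndarray:
        """Return the alignment as a (n_samples, length) array of single chars."""
        if not self.sequences:
            return np.empty((0, 0), dtype="U1")
        return np.array([list(s) for s in self.sequences], dtype="U1")


@dataclass
class SignatureSet:
    """A named, duplicate-free set of feature identifiers."""

    name: str
    members: set[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.members = set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self.members


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(path, dialect: str = "merged_tsv", cohort_id: str | None = None) -> CohortProfile:
    """Read a merged profiler table (rows = features, columns = samples).

    Values given as percentages are auto-detected (any sample column summing
    above 1.5) and divided by 100.  '#'-prefixed lines are ignored.
    """
    if dialect != "merged_tsv":
        raise ValueError(f"unknown dialect: {dialect}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except (ValueError, OSError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ParseError(f"malformed numeric cell at row {row!r}, column {col!r}")
        df[col] = coerced.fillna(0.0)
    feature_ids = [str(x) for x in df.index]
    if len(set(feature_ids)) != len(feature_ids):
        raise ValidationError(f"duplicate feature ids: {sorted(_duplicates(feature_ids))[:5]}")
    values = df.to_numpy(dtype=float)
    if values.size and np.nanmax(values.sum(axis=0), initial=0.0) > 1.5:
        values = values / 100.0
    name = cohort_id if cohort_id is not None else _stem(path)
    return CohortProfile(
        cohort_id=name,
        feature_ids=feature_ids,
        sample_ids=[str(c) for c in df.columns],
        abundances=values,
    )


def write_abundance_table(profile: CohortProfile, path) -> None:
    """Write a profile as a tab-delimited table (fractions, full precision)."""
    df = profile.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.17g", lineterminator="\n")


_METADATA_COLUMNS = [
    "sample_id", "cohort_id", "condition", "stage", "location",
    "age", "sex", "bmi", "primary_tumor_in_situ",
]


def read_metadata(path) -> list[SampleMetadata]:
    """Read per-sample metadata from TSV.

    Required headers: sample_id, cohort_id, condition.  Optional: stage,
    location, age, sex, bmi, primary_tumor_in_situ; missing fields get the
    explicit missing/unknown sentinels.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "cohort_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"metadata missing required columns: {sorted(missing)}")
    records = []
    offenders = []
    for _, row in df.iterrows():
        kwargs = dict(
            sample_id=row["sample_id"],
            cohort_id=row["cohort_id"],
            condition=row["condition"],
        )
        for col, sentinel in (("stage", "unknown"), ("location", "unknown"), ("sex", "missing")):
            val = row.get(col)
            kwargs[col] = sentinel if val is None or pd.isna(val) or val == "" else val
        for col in ("age", "bmi"):
            val = row.get(col)
            kwargs[col] = float("nan") if val is None or pd.isna(val) or val == "" else float(val)
        val = row.get("primary_tumor_in_situ")
        kwargs["primary_tumor_in_situ"] = (
            "not_applicable" if val is None or pd.isna(val) or val == "" else val
        )
        try:
            records.append(SampleMetadata(**kwargs))
        except ValidationError:
            offenders.append(kwargs["sample_id"])
    if offenders:
        raise ValidationError(
            f"metadata invariant violations for samples: {offenders}"
        )
    return records


def write_metadata(records: Sequence[SampleMetadata], path) -> None:
    rows = []
    for m in records:
        rows.append({
            "sample_id": m.sample_id,
            "cohort_id": m.cohort_id,
            "condition": m.condition.value,
            "stage": m.stage.value,
            "location": m.location.value,
            "age": "" if np.isnan(m.age) else f"{m.age:.17g}",
            "sex": m.sex.value,
            "bmi": "" if np.isnan(m.bmi) else f"{m.bmi:.17g}",
            "primary_tumor_in_situ": m.primary_tumor_in_situ,
        })
    pd.DataFrame(rows, columns=_METADATA_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def metadata_frame(records: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Tabular view of metadata records, indexed by sample_id."""
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in records],
            "cohort_id": [m.cohort_id for m in records],
            "condition": [m.condition.value for m in records],
            "stage": [m.stage.value for m in records],
            "location": [m.location.value for m in records],
            "age": [m.age for m in records],
            "sex": [m.sex.value for m in records],
            "bmi": [m.bmi for m in records],
            "primary_tumor_in_situ": [m.primary_tumor_in_situ for m in records],
        }
    )
    return df.set_index("sample_id", drop=False)


def read_msa(path, sgb_id: str | None = None) -> MsaSet:
    """Read an aligned multi-FASTA; upper-case; non-alphabet symbols become N.

    Ambiguous IUPAC bases (R, Y, ...) are treated as missing data at the
    position, not as gaps; the substitution count is logged.
    """
    sample_ids, sequences = [], []
    n_subst = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = []
        for ch in seq:
            if ch in MSA_ALPHABET:
                cleaned.append(ch)
            else:
                cleaned.append("N")
                n_subst += 1
        sample_ids.append(rec.id)
        sequences.append("".join(cleaned))
    if n_subst:
        logger.warning("read_msa(%s): %d non-alphabet symbols mapped to N", path, n_subst)
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise AlignmentError(f"{path}: unequal sequence lengths {sorted(lengths)}")
    return MsaSet(
        sgb_id=sgb_id if sgb_id is not None else _stem(path),
        sample_ids=sample_ids,
        sequences=sequences,
    )


def write_msa(msa: MsaSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(msa.sample_ids, msa.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_signature(path, name: str | None = None) -> SignatureSet:
    """Read a one-column TSV of feature identifiers (header optional-free)."""
    members = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                members.append(line.split("\t")[0])
    return SignatureSet(name=name if name is not None else _stem(path), members=set(members))


def write_signature(sig: SignatureSet, path) -> None:
    with open(path, "w") as fh:
        for m in sorted(sig.members):
            fh.write(f"{m}\n")


def _stem(path) -> str:
    import os

    base = os.path.basename(str(path))
    return base.rsplit(".", 1)[0] if "." in base else base
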