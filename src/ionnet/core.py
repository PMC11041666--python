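"""Shared domain types, table readers/writers and pipeline configuration.

The central container is :class:`IntensityMatrix`, a protein x sample table of
label-free MS intensities.  Missing values are always represented as NaN; raw
zeros from upstream quantification are non-detections, not measurements, and
are converted to NaN at ingestion.  Intensities live either on the raw scale
(strictly positive where present) or on log2 scale, tracked by ``log_scale``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "BaitDesign",
    "ProteinAnnotations",
    "PipelineConfig",
    "read_intensity_table",
    "write_intensity_table",
    "read_design",
    "write_design",
    "log2_transform",
]

#: reserved bait label marking IgG control pulldowns in design tables
IGG_LABEL = "IgG"


@dataclass
class IntensityMatrix:
    """Protein x sample intensity table with explicit missing values.

    Parameters
    ----------
    data
        DataFrame indexed by protein identifier, one column per sample.
        Missing values are NaN.
    log_scale
        ``False`` for raw intensities (strictly positive where present),
        ``True`` once log2-transformed (any finite real where present).
    """

    data: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = sorted(set(self.data.index[self.data.index.duplicated()]))
            raise ValueError(f"duplicate protein ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = sorted(set(self.data.columns[self.data.columns.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dups}")
        self.data = self.data.astype(float)
        if not self.log_scale:
            vals = self.data.to_numpy()
            with np.errstate(invalid="ignore"):
                if np.any(vals[~np.isnan(vals)] <= 0):
                    raise ValueError(
                        "raw-scale intensities must be strictly positive where "
                        "present; convert zeros to missing at ingestion"
                    )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def observed(self) -> pd.DataFrame:
        """Boolean mask of observed (non-missing) cells."""
        return self.data.notna()

    def subset_samples(self, samples: Sequence[str]) -> "IntensityMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return IntensityMatrix(self.data.loc[:, list(samples)].copy(), self.log_scale)


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Apply log2 to a raw-scale matrix (missing entries stay missing)."""
    if matrix.log_scale:
        raise ValueError("matrix is already log2-transformed")
    return IntensityMatrix(np.log2(matrix.data), log_scale=True)


@dataclass
class BaitDesign:
    """Assignment of pulldown samples to baits, bait families and IgG controls.

    Baits sharing a ``family_map`` label form one family (e.g. the three
    inward-rectifier channels Kcnj2/Kcnj3/Kcnj5); whole families are excluded
    together when building complementary-median controls.
    """

    baits: list[str]
    replicate_map: dict[str, list[str]]
    family_map: dict[str, str]
    igg_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sorted(self.replicate_map) != sorted(self.baits):
            raise ValueError("replicate_map keys must equal the bait list")
        seen: dict[str, str] = {}
        for bait, samples in self.replicate_map.items():
            if len(samples) < 2:
                raise ValueError(f"bait {bait!r} has fewer than 2 replicates")
            for s in samples:
                if s in seen:
                    raise ValueError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {bait!r}"
                    )
                seen[s] = bait
        overlap = set(self.igg_samples) & set(seen)
        if overlap:
            raise ValueError(f"IgG samples overlap bait samples: {sorted(overlap)}")
        missing_family = [b for b in self.baits if b not in self.family_map]
        if missing_family:
            raise ValueError(f"baits without family label: {missing_family}")

    @property
    def pulldown_samples(self) -> list[str]:
        """All bait pulldown samples in design order (IgG excluded)."""
        return [s for b in self.baits for s in self.replicate_map[b]]

    def family_of(self, bait: str) -> str:
        if bait not in self.family_map:
            raise KeyError(f"unknown bait: {bait!r}")
        return self.family_map[bait]

    def family_members(self, bait: str) -> list[str]:
        fam = self.family_of(bait)
        return [b for b in self.baits if self.family_map[b] == fam]

    def out_of_family_baits(self, bait: str) -> list[str]:
        fam = self.family_of(bait)
        return [b for b in self.baits if self.family_map[b] != fam]


@dataclass
class ProteinAnnotations:
    """Per-protein sequence coverage (%) and per-(protein, bait) peptide counts."""

    sequence_coverage: pd.Series
    peptide_counts: pd.DataFrame  # proteins x baits, integer

    def __post_init__(self) -> None:
        cov = self.sequence_coverage
        if ((cov < 0) | (cov > 100)).any():
            raise ValueError("sequence coverage must lie in [0, 100]")
        pc = self.peptide_counts
        if (pc.to_numpy() < 0).any():
            raise ValueError("peptide counts must be non-negative")


@dataclass
class PipelineConfig:
    """Tunable thresholds of the interactor-calling pipeline.

    ``fdr_target`` and ``s0`` follow the SAM-style volcano cutoff; per-bait
    overrides allow relaxing or tightening individual baits.  Imputation
    parameters are in units of the per-sample standard deviation on log2 scale.
    """

    fdr_target: float = 0.05
    s0: float = 2.0
    per_bait_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    min_valid_replicates: int = 3
    n_permutations: int = 250
    rng_seed: int = 0
    imputation_width: float = 0.3
    imputation_downshift: float = 1.8
    iqr_zero_policy: str = "error"  # or "shift": median-only proteome scaling

    def __post_init__(self) -> None:
        if not 0 < self.fdr_target < 1:
            raise ValueError("fdr_target must lie in (0, 1)")
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.min_valid_replicates < 2:
            raise ValueError("min_valid_replicates must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.imputation_width <= 0 or self.imputation_downshift < 0:
            raise ValueError("invalid imputation parameters")
        if self.iqr_zero_policy not in ("error", "shift"):
            raise ValueError("iqr_zero_policy must be 'error' or 'shift'")

    def cutoffs_for(self, bait: str) -> tuple[float, float]:
        """(fdr_target, s0) for a bait, honouring per-bait overrides."""
        return self.per_bait_overrides.get(bait, (self.fdr_target, self.s0))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "fdr_target": self.fdr_target,
            "s0": self.s0,
            "per_bait_overrides": {k: list(v) for k, v in self.per_bait_overrides.items()},
            "min_valid_replicates": self.min_valid_replicates,
            "n_permutations": self.n_permutations,
            "rng_seed": self.rng_seed,
            "imputation_width": self.imputation_width,
            "imputation_downshift": self.imputation_downshift,
            "iqr_zero_policy": self.iqr_zero_policy,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        overrides = {
            k: (float(v[0]), float(v[1]))
            for k, v in payload.pop("per_bait_overrides", {}).items()
        }
        return cls(per_bait_overrides=overrides, **payload)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, rng_seed=int(seed))


# ---------------------------------------------------------------------------
# table I/O


def read_intensity_table(
    path: str | Path,
    zero_as_missing: bool = True,
    log_scale: bool = False,
) -> IntensityMatrix:
    """Read a wide tab-delimited intensity table.

    First column holds protein identifiers, remaining columns are samples.
    Zeros are converted to missing when ``zero_as_missing`` (the default):
    zero intensity in label-free MS output means non-detection.  Leading
    comment lines starting with ``#`` are skipped.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate protein ids in {path}: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna() & df.map(lambda v: str(v).strip() != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path} at protein {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if zero_as_missing:
        numeric = numeric.mask(numeric == 0)
    return IntensityMatrix(numeric, log_scale=log_scale)


def write_intensity_table(
    matrix: IntensityMatrix,
    path: str | Path,
    config: PipelineConfig | None = None,
) -> None:
    """Write a matrix back to wide TSV (missing cells left blank)."""
    path = Path(path)
    with path.open("w") as fh:
        if config is not None:
            fh.write(f"# config_hash={config.config_hash()} seed={config.rng_seed}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="protein", na_rep="")


def read_design(path: str | Path) -> BaitDesign:
    """Read a sample design table: columns ``sample``, ``bait``, ``family``.

    Rows with bait equal to ``IgG`` are control pulldowns.  The ``family``
    column may be omitted, in which case every bait is its own family.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample", "bait"}
    if not required <= set(df.columns):
        raise ValueError(f"design table must have columns {sorted(required)}")
    igg = df[df["bait"] == IGG_LABEL]
    rest = df[df["bait"] != IGG_LABEL]
    baits = list(dict.fromkeys(rest["bait"]))
    replicate_map = {b: list(rest.loc[rest["bait"] == b, "sample"]) for b in baits}
    if "family" in df.columns:
        family_map = {}
        for b in baits:
            fams = set(rest.loc[rest["bait"] == b, "family"].dropna())
            family_map[b] = fams.pop() if fams else b
    else:
        family_map = {b: b for b in baits}
    return BaitDesign(baits, replicate_map, family_map, list(igg["sample"]))


def write_design(design: BaitDesign, path: str | Path) -> None:
    rows = [
        {"sample": s, "bait": b, "family": design.family_map[b]}
        for b in design.baits
        for s in design.replicate_map[b]
    ]
    rows += [{"sample": s, "bait": IGG_LABEL, "family": IGG_LABEL} for s in design.igg_samples]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
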