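"""Run-wide configuration: thresholds, toggles and paths.

All tunable constants of the pipeline live here so that a single YAML file
can reproduce a run: the similarity flagging threshold (score >= 5 on the
0-10 scale), the allele-frequency boundaries used by the PM2/BS1/BA1
criteria, the strength at which PM2 is applied, and the reanalysis scan
mode.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Criterion-relevant allele-frequency boundaries.  A frequency update in the
#: knowledge base is only considered material when it crosses one of these.
PM2_AF_DOMINANT = 1e-5
PM2_AF_RECESSIVE = 1e-4
BA1_AF = 0.05


@dataclass
class RunConfig:
    """Everything a pipeline run needs beyond its input data."""

    # paths (optional; CLI fills them in)
    snapshot_dir: str | None = None
    cohort_file: str | None = None
    ontology_file: str | None = None
    ledger_file: str | None = None
    output_dir: str | None = None

    # thresholds
    similarity_threshold: float = 5.0
    pm2_af_dominant: float = PM2_AF_DOMINANT
    pm2_af_recessive: float = PM2_AF_RECESSIVE
    ba1_af: float = BA1_AF
    #: optional per-disease maximum credible allele frequency for BS1,
    #: keyed by disease_id
    bs1_af: dict[str, float] = field(default_factory=dict)

    # toggles
    pm2_strength: str = "supporting"  # ClinGen SVI practice; "moderate" for
    # guideline-literal behaviour
    enable_pp5: bool = False  # deprecated reputable-source criteria
    full_scan: bool = False  # reanalysis: re-evaluate every case daily
    assume_phenotype_fit: bool = False  # treat phenotype fit as satisfied
    # (used when patient HPO terms are not available, e.g. transcribed tables)

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.similarity_threshold <= 10.0):
            raise ValueError("similarity_threshold must be within [0, 10]")
        for name in ("pm2_af_dominant", "pm2_af_recessive", "ba1_af"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a frequency in [0, 1]")
        if self.pm2_strength not in ("supporting", "moderate"):
            raise ValueError("pm2_strength must be 'supporting' or 'moderate'")

    @property
    def frequency_boundaries(self) -> tuple[float, ...]:
        """Sorted AF boundaries that make a frequency change material."""
        bounds = {self.pm2_af_dominant, self.pm2_af_recessive, self.ba1_af}
        bounds.update(self.bs1_af.values())
        return tuple(sorted(bounds))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Errors shared across modules
# ---------------------------------------------------------------------------


class RetriageError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(RetriageError):
    """A record in an input file violates the documented schema."""


class DateOrderingError(RetriageError):
    """Dated inputs supplied out of chronological order."""


class HgvsParseError(RetriageError):
    """An HGVS c. description could not be parsed."""


class EvidenceConflictError(RetriageError):
    """Mutually exclusive evidence flags supplied for one variant."""


class UnknownTermError(RetriageError):
    """An ontology term id is not present in the loaded ontology."""


class EmptyPhenotypeError(RetriageError):
    """No usable phenotype terms remain after dropping unknown ones."""
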