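"""Core in-memory containers shared across the pipeline stages.

The pipeline passes three kinds of objects between stages: a genotype
matrix (additive minor-allele dosages with variant/sample metadata), a
phenotype table (diagnosis, covariates, ICV and raw structure volumes),
and small result records (QC report, module partition). All tabular
metadata lives in pandas DataFrames; dosages are a dense float array
with NaN marking missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "QcReport",
    "ModulePartition",
]

#: required columns of :attr:`GenotypeMatrix.variant_meta`
VARIANT_COLUMNS = ("snp", "chrom", "pos", "a1", "a2", "is_x")
#: required columns of :attr:`GenotypeMatrix.sample_meta`
SAMPLE_COLUMNS = ("sample", "reported_sex")


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix.

    Parameters
    ----------
    dosages
        Array of shape ``(n_samples, n_variants)`` with values in
        ``{0.0, 1.0, 2.0}`` and ``NaN`` for missing calls. Dosage counts
        copies of the minor allele (``a2``).
    variant_meta
        One row per variant: ``snp`` (unique id), ``chrom`` (string,
        ``"X"`` for the sex chromosome), ``pos`` (1-based bp), ``a1``/``a2``
        (major/minor allele letters), ``is_x`` (bool).
    sample_meta
        One row per sample: ``sample`` (unique id), ``reported_sex``
        (``"M"``/``"F"``).
    """

    dosages: np.ndarray
    variant_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.sample_meta) != n or len(self.variant_meta) != m:
            raise ValueError("metadata length does not match dosage shape")
        for col in VARIANT_COLUMNS:
            if col not in self.variant_meta.columns:
                raise ValueError(f"variant_meta missing column {col!r}")
        for col in SAMPLE_COLUMNS:
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing column {col!r}")
        if self.variant_meta["snp"].duplicated().any():
            raise ValueError("variant ids must be unique")
        if self.sample_meta["sample"].duplicated().any():
            raise ValueError("sample ids must be unique")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2} or NaN")
        self.variant_meta = self.variant_meta.reset_index(drop=True)
        self.sample_meta = self.sample_meta.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> pd.Series:
        return self.sample_meta["sample"]

    @property
    def variant_ids(self) -> pd.Series:
        return self.variant_meta["snp"]

    def variant_index(self, snps: Iterable[str]) -> np.ndarray:
        """Column indices for the given variant ids (errors on unknown ids)."""
        lookup = pd.Series(
            np.arange(self.n_variants), index=self.variant_meta["snp"]
        )
        snps = list(snps)
        missing = [s for s in snps if s not in lookup.index]
        if missing:
            raise KeyError(f"unknown variant id(s): {missing[:5]}")
        return lookup[snps].to_numpy()

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant from non-missing dosages.

        Folded to [0, 0.5]: the dosage coding targets the minor allele at
        simulation time, but defects or subsetting can push a frequency
        past 0.5.
        """
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset(
        self,
        samples: Sequence[int] | np.ndarray | None = None,
        variants: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Positional subset; returns a new matrix (copy)."""
        s = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        v = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(s, v)].copy(),
            variant_meta=self.variant_meta.iloc[v].reset_index(drop=True),
            sample_meta=self.sample_meta.iloc[s].reset_index(drop=True),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(),
            self.variant_meta.copy(),
            self.sample_meta.copy(),
        )


@dataclass
class PhenotypeTable:
    """Per-sample diagnosis, covariates, ICV and raw structure volumes.

    ``data`` is indexed by sample id and holds the clinical columns
    (``diagnosis`` in {"AD","NC"}, ``age`` years, ``sex`` 0=female/1=male,
    ``education`` years, optional ``MMSE``/``CDRSB`` scores, ``icv`` mm^3)
    followed by one column of raw volume (mm^3) per phenotype listed in
    ``roi_columns``.
    """

    data: pd.DataFrame
    roi_columns: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in self.roi_columns if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing ROI columns: {missing[:5]}")
        for col in ("diagnosis", "age", "sex", "education", "icv"):
            if col not in self.data.columns:
                raise ValueError(f"phenotype table missing column {col!r}")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def volumes(self) -> pd.DataFrame:
        """Raw ROI volume block (samples x phenotypes)."""
        return self.data[self.roi_columns]

    def covariates(self) -> pd.DataFrame:
        """Age/sex/education covariate block used by the association models."""
        return self.data[["age", "sex", "education"]].astype(float)


@dataclass
class QcReport:
    """Record of removals with one primary reason code each.

    Reason codes: samples ``call_rate | sex_mismatch | ibd``; variants
    ``call_rate | hwe | maf | ld_prune``.
    """

    removed_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample", "reason"])
    )
    removed_variants: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )
    thresholds: dict = field(default_factory=dict)

    def add_samples(self, ids: Iterable[str], reason: str) -> None:
        new = pd.DataFrame({"sample": list(ids), "reason": reason})
        if len(new):
            self.removed_samples = pd.concat(
                [self.removed_samples, new], ignore_index=True
            )

    def add_variants(self, ids: Iterable[str], reason: str) -> None:
        new = pd.DataFrame({"snp": list(ids), "reason": reason})
        if len(new):
            self.removed_variants = pd.concat(
                [self.removed_variants, new], ignore_index=True
            )

    def to_dict(self) -> dict:
        return {
            "thresholds": dict(self.thresholds),
            "removed_samples": self.removed_samples.to_dict(orient="records"),
            "removed_variants": self.removed_variants.to_dict(orient="records"),
        }


@dataclass
class ModulePartition:
    """Assignment of phenotypes to modules from the hierarchical cut.

    ``assignment`` maps phenotype id -> module id in ``1..k``. Module ids
    are renumbered so that module 1 appears first in roster order.
    ``heights`` records the complete-linkage merge heights (ascending).
    """

    assignment: dict[str, int]
    k: int
    heights: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        mods = set(self.assignment.values())
        if len(mods) != self.k or mods != set(range(1, self.k + 1)):
            raise ValueError("module ids must be exactly 1..k")

    def members(self, module: int) -> list[str]:
        return [p for p, m in self.assignment.items() if m == module]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {m: 0 for m in range(1, self.k + 1)}
        for m in self.assignment.values():
            out[m] += 1
        return out
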