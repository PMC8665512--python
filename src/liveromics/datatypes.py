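"""Core in-memory containers shared by every pipeline stage.

All omics matrices are features x samples. Missing entries are carried as
NaN in the value frame; the boolean ``mask`` (True = missing) is derived
from it so the two can never disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


@dataclass
class OmicsMatrix:
    """Feature x sample numeric matrix with explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID with sample IDs as columns.
        Missing entries are NaN.
    value_domain
        ``"log-abundance"`` (unbounded) or ``"beta"`` (observed entries
        must lie in [0, 1]).
    """

    values: pd.DataFrame
    value_domain: str = "log-abundance"

    def __post_init__(self) -> None:
        if self.value_domain not in ("log-abundance", "beta", "linear"):
            raise ValidationError(f"unknown value_domain {self.value_domain!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        vals = self.values.to_numpy(dtype=float)
        if self.value_domain == "beta":
            bad = np.argwhere((vals < 0) | (vals > 1))
            if bad.size:
                r, c = bad[0]
                raise ValidationError(
                    f"beta value out of [0,1] at feature {idx[r]!r}, "
                    f"sample {cols[c]!r}: {vals[r, c]}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the entry is missing."""
        return self.values.isna()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: pd.DataFrame) -> "OmicsMatrix":
        return OmicsMatrix(values=values, value_domain=self.value_domain)


@dataclass
class PathwayDB:
    """Named gene sets: pathway name -> (description, frozenset of genes)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, genes) in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"pathway {name!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def genes(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def items(self):
        return self.sets.items()


TNM_STAGES = ("I", "II", "III", "IV")
PHENOTYPES = ("MI", "MA")

CLINICAL_COLUMNS = (
    "sample",
    "rfs_months",
    "rfs_event",
    "tnm_stage",
    "afp_high",
    "thrombus",
    "phenotype",
)


@dataclass
class ClinicalTable:
    """Per-sample outcome/covariate table for relapse and survival analyses.

    One row per sample; columns: sample, rfs_months, rfs_event (0/1),
    tnm_stage (I-IV), afp_high (0/1), thrombus (0/1), phenotype
    (MI / MA / NaN).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = set(CLINICAL_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
        if df["sample"].duplicated().any():
            dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
            raise ValidationError(f"duplicate sample in clinical table: {dup!r}")
        if (df["rfs_months"] < 0).any():
            s = df.loc[df["rfs_months"] < 0, "sample"].iloc[0]
            raise ValidationError(f"negative rfs_months for sample {s!r}")
        if not df["rfs_event"].isin([0, 1]).all():
            s = df.loc[~df["rfs_event"].isin([0, 1]), "sample"].iloc[0]
            raise ValidationError(f"rfs_event not in {{0,1}} for sample {s!r}")
        if not df["tnm_stage"].isin(TNM_STAGES).all():
            bad = df.loc[~df["tnm_stage"].isin(TNM_STAGES), "tnm_stage"].iloc[0]
            raise ValidationError(f"unknown TNM stage {bad!r}")
        for col in ("afp_high", "thrombus"):
            if not df[col].isin([0, 1]).all():
                raise ValidationError(f"{col} must be 0/1")
        ok_ph = df["phenotype"].isna() | df["phenotype"].isin(PHENOTYPES)
        if not ok_ph.all():
            bad = df.loc[~ok_ph, "phenotype"].iloc[0]
            raise ValidationError(f"unknown phenotype {bad!r}")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample"])

    def subset(self, samples) -> "ClinicalTable":
        samples = list(samples)
        sub = self.frame[self.frame["sample"].isin(samples)].copy()
        order = {s: i for i, s in enumerate(samples)}
        sub = sub.sort_values("sample", key=lambda s: s.map(order))
        return ClinicalTable(sub.reset_index(drop=True))


@dataclass
class SubgroupAssignment:
    """Consensus-clustering result: labels, consensus matrix, K trace."""

    labels: pd.Series  # index = sample IDs, values in 1..K
    K: int
    consensus: pd.DataFrame  # sample x sample in [0, 1]
    selection_trace: pd.DataFrame  # per-K consensus-CDF area and delta-area

    def __post_init__(self) -> None:
        c = self.consensus.to_numpy()
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValidationError("consensus matrix not symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValidationError("consensus diagonal not 1")
        if ((c < -1e-12) | (c > 1 + 1e-12)).any():
            raise ValidationError("consensus entries outside [0,1]")
        if set(self.labels.index) != set(self.consensus.index):
            raise ValidationError("labels do not cover consensus samples")
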