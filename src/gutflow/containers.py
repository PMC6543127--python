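"""Core in-memory containers shared across the pipeline.

Every stage operates on features-by-samples tables held as pandas DataFrames
wrapped in :class:`AbundanceMatrix`, which records whether values are read
depths, integer counts, or relative fractions (columns summing to one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_KINDS = ("depth", "count", "relative")

#: column sums of a relative matrix must equal 1 within this tolerance
REL_TOL = 1e-9


@dataclass
class AbundanceMatrix:
    """Features x samples numeric table.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id, one column per sample id.
    kind:
        One of ``"depth"`` (length-normalised read depth), ``"count"``
        (integer counts) or ``"relative"`` (per-sample fractions summing
        to 1).
    """

    data: pd.DataFrame
    kind: str = "depth"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy(dtype=float, copy=False)
        if values.size:
            if np.isnan(values).any():
                r, c = np.argwhere(np.isnan(values))[0]
                raise ValueError(
                    f"missing value at feature {self.data.index[r]!r}, "
                    f"sample {self.data.columns[c]!r}"
                )
            if (values < 0).any():
                r, c = np.argwhere(values < 0)[0]
                raise ValueError(
                    f"negative value at feature {self.data.index[r]!r}, "
                    f"sample {self.data.columns[c]!r}"
                )
            if self.kind == "relative" and self.data.shape[0] > 0:
                sums = values.sum(axis=0)
                bad = np.abs(sums - 1.0) > 1e-6
                if bad.any():
                    j = int(np.argmax(bad))
                    raise ValueError(
                        f"relative matrix column {self.data.columns[j]!r} "
                        f"sums to {sums[j]:.6g}, expected 1"
                    )

    @classmethod
    def unchecked(cls, data: pd.DataFrame, kind: str) -> "AbundanceMatrix":
        """Construct without validation (for feature subsets of relative
        matrices, whose columns legitimately no longer sum to 1)."""
        out = cls.__new__(cls)
        out.data = data
        out.kind = kind
        return out

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        return AbundanceMatrix.unchecked(self.data.loc[:, list(sample_ids)], self.kind)

    def subset_features(self, feature_ids) -> "AbundanceMatrix":
        return AbundanceMatrix.unchecked(self.data.loc[list(feature_ids)], self.kind)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table: unique ``sample_id`` index, nonempty ``group``."""
    if "group" not in meta.columns:
        raise ValueError("metadata must contain a 'group' column")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    if meta["group"].isna().any() or (meta["group"].astype(str) == "").any():
        raise ValueError("empty group labels in metadata")
    return meta


def group_masks(meta: pd.DataFrame, sample_ids,
                case: str = "case", control: str = "control"):
    """Boolean case/control masks aligned to ``sample_ids``."""
    groups = meta.loc[list(sample_ids), "group"].to_numpy()
    case_mask = groups == case
    control_mask = groups == control
    if not case_mask.any() or not control_mask.any():
        raise ValueError(
            f"both groups {case!r} and {control!r} must be present; "
            f"found {sorted(set(groups))}"
        )
    return case_mask, control_mask


@dataclass
class PeakTable:
    """LC-MS peak-area table for one ionisation mode and compartment.

    ``meta`` carries per-feature annotation (compound name, mode,
    compartment, retention time in minutes, neutral mass in Da) and
    ``areas`` the nonnegative peak areas, features x samples.
    """

    meta: pd.DataFrame
    areas: pd.DataFrame
    normalized: bool = False

    META_COLUMNS = ("compound", "mode", "compartment", "rt_min", "mass_da")

    def __post_init__(self) -> None:
        missing = [c for c in self.META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"peak table metadata missing columns: {missing}")
        if not self.meta.index.equals(self.areas.index):
            raise ValueError("peak table meta and areas must share feature index")
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("negative peak areas")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.areas.index)


@dataclass
class GroundTruth:
    """Planted structure emitted alongside every synthetic study."""

    cag_membership: dict[str, str] = field(default_factory=dict)
    differential_features: dict[str, dict[str, int]] = field(default_factory=dict)
    enterotype_label: dict[str, int] = field(default_factory=dict)
    taxon_metabolite_links: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cag_membership": self.cag_membership,
            "differential_features": self.differential_features,
            "enterotype_label": self.enterotype_label,
            "taxon_metabolite_links": [list(t) for t in self.taxon_metabolite_links],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            cag_membership=dict(d.get("cag_membership", {})),
            differential_features={
                k: dict(v) for k, v in d.get("differential_features", {}).items()
            },
            enterotype_label={k: int(v) for k, v in d.get("enterotype_label", {}).items()},
            taxon_metabolite_links=[
                (a, b, float(c)) for a, b, c in d.get("taxon_metabolite_links", [])
            ],
        )
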