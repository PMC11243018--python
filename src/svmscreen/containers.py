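"""Core data containers for LC-MS screening pipelines.

A feature table is a variables x samples matrix of chromatographic peak
intensities.  Each variable (feature) is one aligned peak characterised by
an accurate mass-to-charge ratio (``mz``) and a retention time in minutes
(``rt_min``); each sample carries a group label — a spiked concentration
level in ng/mL, ``QC`` for pooled quality-control injections, or ``blank``.
Variable identifiers follow the ``M{nominal m/z}T{RT in seconds}`` dialect
common to XCMS-style peak pickers (e.g. ``M320T382``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: role values for feature-table variables
ROLE_FEATURE = "feature"
ROLE_INTERNAL_STANDARD = "internal_standard"

QC_GROUP = "QC"
BLANK_GROUP = "blank"


def variable_id(mz: float, rt_min: float) -> str:
    """Build an ``M{m/z}T{seconds}`` identifier from mass and retention time."""
    return f"M{round(mz):d}T{round(rt_min * 60.0):d}"


@dataclass
class FeatureTable:
    """Peak-intensity matrix with variable and sample annotations.

    Parameters
    ----------
    intensities
        DataFrame of shape (n_variables, n_samples); index = variable ids,
        columns = sample ids.
    variables
        Per-variable metadata indexed like ``intensities``; must contain
        ``mz``, ``rt_min`` and ``role`` columns.
    samples
        Per-sample metadata indexed by sample id; must contain ``group``
        (string label) and ``sample_type`` columns.
    """

    intensities: pd.DataFrame
    variables: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.variables.index):
            raise ValueError("variable metadata index does not match intensity rows")
        if not self.intensities.columns.equals(self.samples.index):
            raise ValueError("sample metadata index does not match intensity columns")
        for col in ("mz", "rt_min"):
            if col not in self.variables.columns:
                raise ValueError(f"variable metadata lacks required column {col!r}")
        if "role" not in self.variables.columns:
            self.variables = self.variables.assign(role=ROLE_FEATURE)
        for col in ("group", "sample_type"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_variables(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def variable_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def feature_ids(self) -> pd.Index:
        """Variable ids excluding internal standards."""
        keep = self.variables["role"] != ROLE_INTERNAL_STANDARD
        return self.variables.index[keep]

    @property
    def internal_standard_ids(self) -> pd.Index:
        keep = self.variables["role"] == ROLE_INTERNAL_STANDARD
        return self.variables.index[keep]

    def group_samples(self, group: str) -> list[str]:
        """Sample ids belonging to a group label."""
        return list(self.samples.index[self.samples["group"] == str(group)])

    def concentration_groups(self) -> list[str]:
        """Concentration group labels, sorted numerically ascending."""
        labels = {
            g for g in self.samples["group"].unique() if g not in (QC_GROUP, BLANK_GROUP)
        }
        return sorted(labels, key=float)

    def group_matrix(self, group: str) -> pd.DataFrame:
        return self.intensities[self.group_samples(group)]

    def subset(self, variable_ids) -> "FeatureTable":
        ids = pd.Index(variable_ids)
        return FeatureTable(
            self.intensities.loc[ids].copy(),
            self.variables.loc[ids].copy(),
            self.samples.copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.variables.copy(), self.samples.copy()
        )

    # -- I/O ---------------------------------------------------------------
    def write(self, table_path, samples_path) -> None:
        """Write intensities+variable metadata and the sample sidecar as TSV."""
        out = pd.concat([self.variables[["mz", "rt_min", "role"]], self.intensities], axis=1)
        out.index.name = "variable_id"
        out.to_csv(table_path, sep="\t")
        meta = self.samples.copy()
        meta.index.name = "sample_id"
        meta.to_csv(samples_path, sep="\t")

    @classmethod
    def read(cls, table_path, samples_path) -> "FeatureTable":
        raw = pd.read_csv(table_path, sep="\t", index_col="variable_id")
        variables = raw[["mz", "rt_min", "role"]]
        intensities = raw.drop(columns=["mz", "rt_min", "role"])
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        samples["group"] = samples["group"].astype(str)
        return cls(intensities, variables, samples)


@dataclass
class CompoundLibrary:
    """Reference compound records: name, category, exact [M+H]+ mass, RT.

    The bundled default covers 124 pesticide and veterinary-drug residues
    (69 pesticides, 55 veterinary drugs) with exact protonated masses and
    retention times on a 14-min reversed-phase gradient.
    """

    records: pd.DataFrame

    REQUIRED = ("name", "category", "exact_mass", "rt_min")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.records.columns:
                raise ValueError(f"library lacks required column {col!r}")
        if "no" not in self.records.columns:
            self.records = self.records.assign(no=np.arange(1, len(self.records) + 1))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_distinct(self) -> int:
        """Distinct compounds by (name, exact mass); duplicate entries collapse."""
        return len(
            self.records.assign(_k=self.records["name"].str.lower())
            .drop_duplicates(subset=["_k", "exact_mass"])
        )

    def write(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def read(cls, path) -> "CompoundLibrary":
        return cls(pd.read_csv(path))

    @classmethod
    def bundled(cls) -> "CompoundLibrary":
        """The built-in 124-compound pesticide & veterinary drug library."""
        with importlib.resources.files("svmscreen.data").joinpath(
            "pvd_library.csv"
        ).open() as fh:
            return cls(pd.read_csv(fh))


def load_marker_observations() -> pd.DataFrame:
    """Published screening observations for the bundled library.

    One row per confirmed marker variable: the variable id, matched
    compound, VIP and weight-squared scores from the two one-vs-rest
    contrasts, the observed m/z and retention time, the reported ppm mass
    error and the method LOD in ug/kg.
    """
    with importlib.resources.files("svmscreen.data").joinpath(
        "marker_observations.csv"
    ).open() as fh:
        return pd.read_csv(fh)


@dataclass
class GroundTruth:
    """Provenance of synthetic variables, for recall / false-positive scoring."""

    marker_compounds: dict[str, str]  # variable id -> library compound name
    background_ids: set[str] = field(default_factory=set)
    erratic_ids: set[str] = field(default_factory=set)
    recoveries: pd.DataFrame | None = None  # per sample: r_is1, r_is2 (percent)

    def __post_init__(self) -> None:
        marker = set(self.marker_compounds)
        if marker & self.background_ids or marker & self.erratic_ids:
            raise ValueError("marker/background/erratic id sets must be disjoint")
        if self.background_ids & self.erratic_ids:
            raise ValueError("background and erratic id sets must be disjoint")

    @property
    def marker_ids(self) -> set[str]:
        return set(self.marker_compounds)

    def write(self, path) -> None:
        rows = [
            {"variable_id": v, "kind": "marker", "compound": c}
            for v, c in self.marker_compounds.items()
        ]
        rows += [
            {"variable_id": v, "kind": "background", "compound": ""}
            for v in sorted(self.background_ids)
        ]
        rows += [
            {"variable_id": v, "kind": "erratic", "compound": ""}
            for v in sorted(self.erratic_ids)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
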