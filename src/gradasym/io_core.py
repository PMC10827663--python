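"""Readers, writers, and validated domain containers.

The coordinate frame of every downstream map is the
:class:`ParcellationScheme`: a bilaterally matched parcellation with 180
parcels per hemisphere, a homolog (mirror-parcel) bijection between
hemispheres, and a 12-network assignment. Subject phenotypes live in a
:class:`CohortTable`; exclusion rules (age > 40, FIQ < 70, mean framewise
displacement > 0.3 mm) set flags but never drop rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import DimensionError, IntegrityError, SchemaError

NETWORKS_12 = (
    "Vis1", "Vis2", "SMN", "CON", "DAN", "Lan",
    "FPN", "Aud", "DMN", "PMN", "VMN", "OAN",
)

GROUPS = ("autism", "NAI")

PHENOTYPE_REQUIRED = ("subject_id", "group", "age", "site")
PHENOTYPE_OPTIONAL = (
    "fiq", "mean_fd", "ados_total", "ados_comm", "ados_social", "ados_rrb",
    "matrix_path",
)

PARCELLATION_COLUMNS = ("parcel_id", "parcel_name", "hemisphere", "homolog_id", "network")


@dataclass(frozen=True)
class ParcellationScheme:
    """Bilaterally matched parcellation.

    Parameters
    ----------
    table
        One row per parcel with columns ``parcel_id`` (0..n-1),
        ``parcel_name``, ``hemisphere`` ('left'/'right'), ``homolog_id``
        (index of the mirror parcel) and ``network``.
    networks
        The closed set of admissible network labels.
    """

    table: pd.DataFrame
    networks: tuple[str, ...] = NETWORKS_12

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PARCELLATION_COLUMNS if c not in t.columns]
        if missing:
            raise SchemaError(f"parcellation table missing columns: {missing}")
        n = len(t)
        if not np.array_equal(np.asarray(t["parcel_id"]), np.arange(n)):
            raise IntegrityError("parcel_id must be 0..n-1 in row order")
        hemis = set(t["hemisphere"])
        if hemis != {"left", "right"}:
            raise IntegrityError(f"hemisphere labels must be left/right, got {sorted(hemis)}")
        n_left = int((t["hemisphere"] == "left").sum())
        n_right = int((t["hemisphere"] == "right").sum())
        if n_left != n_right:
            raise IntegrityError(f"unequal hemispheres: {n_left} left vs {n_right} right")
        hom = np.asarray(t["homolog_id"], dtype=int)
        hemi = np.asarray(t["hemisphere"])
        bad = [
            i for i in range(n)
            if not (0 <= hom[i] < n) or hemi[hom[i]] == hemi[i] or hom[hom[i]] != i
        ]
        if bad:
            raise IntegrityError(
                f"homolog map is not a symmetric cross-hemisphere bijection; offending rows: {bad[:10]}"
            )
        # homologs must share a network, otherwise pair-level maps are ill-defined
        net = np.asarray(t["network"])
        unknown = sorted(set(net) - set(self.networks))
        if unknown:
            raise IntegrityError(f"unknown network label(s): {unknown}")
        mism = [i for i in range(n) if net[hom[i]] != net[i]]
        if mism:
            raise IntegrityError(f"homolog pairs with mismatched networks at rows: {mism[:10]}")

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def n_pairs(self) -> int:
        return self.n_parcels // 2

    @property
    def left_indices(self) -> np.ndarray:
        """Left-parcel indices in homolog-pair order (pair i = i-th left parcel)."""
        return np.flatnonzero(np.asarray(self.table["hemisphere"]) == "left")

    @property
    def right_indices(self) -> np.ndarray:
        """Right-parcel indices ordered so right_indices[i] is the homolog of left_indices[i]."""
        hom = np.asarray(self.table["homolog_id"], dtype=int)
        return hom[self.left_indices]

    @property
    def pair_networks(self) -> np.ndarray:
        """Network label of each homolog pair (shared by both members)."""
        return np.asarray(self.table["network"])[self.left_indices]

    @property
    def pair_names(self) -> np.ndarray:
        return np.asarray(self.table["parcel_name"])[self.left_indices]


@dataclass
class CohortTable:
    """Validated subject phenotypes with exclusion flags.

    The ``excluded`` column is advisory: rows are flagged, never removed,
    so callers decide what enters each analysis. ``matrices`` optionally
    holds per-subject connectivity arrays keyed by subject id.
    """

    table: pd.DataFrame
    matrices: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        t = self.table
        missing = [c for c in PHENOTYPE_REQUIRED if c not in t.columns]
        if missing:
            raise SchemaError(f"phenotype table missing required column(s): {missing}")
        dup = t["subject_id"][t["subject_id"].duplicated()].tolist()
        if dup:
            raise IntegrityError(f"duplicate subject_id(s): {dup[:10]}")
        bad_group = sorted(set(t["group"]) - set(GROUPS))
        if bad_group:
            raise IntegrityError(f"unknown group label(s): {bad_group}; expected {GROUPS}")
        if "mean_fd" in t.columns and (pd.to_numeric(t["mean_fd"], errors="coerce") < 0).any():
            raise IntegrityError("mean_fd must be non-negative")

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def included(self) -> pd.DataFrame:
        """Rows passing all exclusion rules."""
        if "excluded" not in self.table.columns:
            return self.table
        return self.table[~self.table["excluded"]]


def apply_exclusion_flags(table: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Set the exclusion flag columns in place-free fashion (returns a copy).

    Rules: age above the configured maximum, FIQ below the configured
    minimum, mean FD above the motion threshold. Missing optional values
    never trigger a flag.
    """
    t = table.copy()
    age = pd.to_numeric(t["age"], errors="coerce")
    t["excl_age"] = age > config.max_age_years
    if "fiq" in t.columns:
        fiq = pd.to_numeric(t["fiq"], errors="coerce")
        t["excl_fiq"] = fiq.notna() & (fiq < config.min_fiq)
    else:
        t["excl_fiq"] = False
    if "mean_fd" in t.columns:
        fd = pd.to_numeric(t["mean_fd"], errors="coerce")
        t["excl_fd"] = fd.notna() & (fd > config.fd_threshold_mm)
    else:
        t["excl_fd"] = False
    t["excluded"] = t["excl_age"] | t["excl_fiq"] | t["excl_fd"]
    t["age_group"] = age.map(config.age_group_of)
    return t


def load_phenotype(path: str | Path, config: PipelineConfig | None = None) -> CohortTable:
    """Read a phenotype CSV/TSV, validate it, and assign age groups and flags."""
    config = config or PipelineConfig()
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    t = pd.read_csv(path, sep=sep)
    missing = [c for c in PHENOTYPE_REQUIRED if c not in t.columns]
    if missing:
        raise SchemaError(f"phenotype file {path} missing required column(s): {missing}")
    t["subject_id"] = t["subject_id"].astype(str)
    t = apply_exclusion_flags(t, config)
    return CohortTable(t)


def load_parcellation(path: str | Path) -> ParcellationScheme:
    """Read a parcellation TSV and verify its structural invariants."""
    t = pd.read_csv(path, sep="\t")
    return ParcellationScheme(t)


def canonical_parcellation_table(
    n_per_hemi: int, networks: np.ndarray, names: np.ndarray | None = None
) -> pd.DataFrame:
    """Canonical ordering: parcels 0..n-1 left, n..2n-1 right, homolog = i +/- n."""
    n = n_per_hemi
    if names is None:
        names = np.array([f"P{i:03d}" for i in range(n)])
    return pd.DataFrame(
        {
            "parcel_id": np.arange(2 * n),
            "parcel_name": np.concatenate([names, names]),
            "hemisphere": ["left"] * n + ["right"] * n,
            "homolog_id": np.concatenate([np.arange(n) + n, np.arange(n)]),
            "network": np.concatenate([networks, networks]),
        }
    )


def read_matrix(path: str | Path, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a dense numeric matrix.

    Text (``.csv``, ``.tsv``, ``.txt``) and NumPy binary (``.npy``)
    containers are both honored, chosen by extension.
    """
    path = Path(path)
    if path.suffix == ".npy":
        m = np.load(path)
    else:
        delimiter = "," if path.suffix.lower() == ".csv" else None
        try:
            m = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        except ValueError as exc:
            raise SchemaError(f"non-numeric content in matrix file {path}: {exc}") from exc
    if expected_shape is not None and m.shape != tuple(expected_shape):
        raise DimensionError(
            f"matrix in {path} has shape {m.shape}, expected {tuple(expected_shape)}"
        )
    return np.asarray(m, dtype=float)


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write a matrix; text containers round-trip at full double precision."""
    path = Path(path)
    matrix = np.asarray(matrix, dtype=float)
    if path.suffix == ".npy":
        np.save(path, matrix)
    else:
        delimiter = "," if path.suffix.lower() == ".csv" else " "
        np.savetxt(path, matrix, delimiter=delimiter, fmt="%.17g")
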