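"""Core in-memory containers shared across the pipeline.

A section is represented by four aligned objects: a :class:`SpotGrid`
(the capture-spot lattice, coordinates in micrometres), a
:class:`CountMatrix` (genes x spots, sparse non-negative integers), a
:class:`CompartmentMap` (per-spot tissue label, with optional tumor/gland
zone sub-labels), and optionally a :class:`CellTable` of segmented cell
centroids with marker status.  All containers validate their invariants
on construction and refuse to coerce malformed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

COMPARTMENTS = (
    "normal_gland",
    "tumor",
    "muscularis",
    "submucosa",
    "lymphoid_follicle",
)
TUMOR_ZONES = ("T1", "T2", "T3", "T4", "T5")
GLAND_ZONES = ("G1", "G2", "G3", "G4")
LATTICES = ("hex", "square")

#: Cell classes as plotted in center-to-edge density profiles.
CELL_CLASSES = ("CD44+", "PTN+", "CD44+PTN+")

#: marker-class name -> (CD44_pos, PTN_pos)
CLASS_FLAGS = {
    "CD44+": (True, False),
    "PTN+": (False, True),
    "CD44+PTN+": (True, True),
    "other": (False, False),
}


@dataclass(frozen=True)
class SpotGrid:
    """Geometry of one section's spot lattice.

    Coordinates are in micrometres, x rightward and y downward (image
    convention).  ``array_row``/``array_col`` are 0-based lattice indices;
    for a hex lattice odd rows are offset by half a pitch.
    """

    barcodes: np.ndarray
    array_row: np.ndarray
    array_col: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    lattice: str
    pitch_um: float
    spot_diameter_um: float

    def __post_init__(self) -> None:
        bc = np.asarray(self.barcodes, dtype=object)
        n = bc.size
        if len(set(bc.tolist())) != n:
            raise ValueError("SpotGrid: duplicate barcodes")
        for name in ("array_row", "array_col", "x_um", "y_um"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"SpotGrid: field {name} has wrong length")
        if not (np.all(np.isfinite(self.x_um)) and np.all(np.isfinite(self.y_um))):
            raise ValueError("SpotGrid: non-finite coordinates")
        if self.lattice not in LATTICES:
            raise ValueError(f"SpotGrid: lattice must be one of {LATTICES}")
        if not self.pitch_um > 0:
            raise ValueError("SpotGrid: pitch_um must be positive")
        if not 0 < self.spot_diameter_um <= self.pitch_um:
            raise ValueError("SpotGrid: spot diameter must be in (0, pitch]")

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of spot-center coordinates in μm."""
        return np.column_stack([self.x_um, self.y_um])

    def barcode_index(self) -> dict:
        return {b: i for i, b in enumerate(self.barcodes)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "array_row": self.array_row,
                "array_col": self.array_col,
                "x_um": self.x_um,
                "y_um": self.y_um,
            }
        )

    def translated(self, dx_um: float, dy_um: float) -> "SpotGrid":
        """Same lattice rigidly shifted; distances are unaffected."""
        return SpotGrid(
            barcodes=self.barcodes,
            array_row=self.array_row,
            array_col=self.array_col,
            x_um=np.asarray(self.x_um) + dx_um,
            y_um=np.asarray(self.y_um) + dy_um,
            lattice=self.lattice,
            pitch_um=self.pitch_um,
            spot_diameter_um=self.spot_diameter_um,
        )


@dataclass(frozen=True)
class CountMatrix:
    """Genes x spots matrix of non-negative integer counts (CSR sparse)."""

    gene_ids: np.ndarray
    barcodes: np.ndarray
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        genes = np.asarray(self.gene_ids, dtype=object)
        bcs = np.asarray(self.barcodes, dtype=object)
        if len(set(genes.tolist())) != genes.size:
            raise ValueError("CountMatrix: gene_ids not unique")
        vals = self.values
        if not sp.issparse(vals):
            raise ValueError("CountMatrix: values must be sparse")
        if vals.shape != (genes.size, bcs.size):
            raise ValueError(
                f"CountMatrix: shape {vals.shape} inconsistent with "
                f"{genes.size} genes x {bcs.size} barcodes"
            )
        if vals.nnz and vals.data.min() < 0:
            raise ValueError("CountMatrix: negative entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def gene_vector(self, gene: str) -> np.ndarray:
        """Dense per-spot counts for one gene; KeyError if absent."""
        idx = self.gene_index()
        if gene not in idx:
            raise KeyError(f"gene {gene!r} not in count matrix")
        return np.asarray(self.values[idx[gene], :].todense()).ravel()

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass(frozen=True)
class CompartmentMap:
    """Per-spot tissue compartment, with optional zone sub-labels.

    ``frame`` is indexed by barcode with columns ``compartment`` and
    ``zone`` (zone is NA outside zoned compartments).  Tumor zones T1-T5
    run innermost to outermost; gland zones G1-G4 are allowed on
    normal_gland spots.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if "compartment" not in df.columns:
            raise ValueError("CompartmentMap: missing 'compartment' column")
        if df.index.has_duplicates:
            raise ValueError("CompartmentMap: duplicate barcodes")
        bad = set(df["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValueError(
                f"unknown compartment label(s) {sorted(bad)}; "
                f"allowed: {list(COMPARTMENTS)}"
            )
        if "zone" not in df.columns:
            df = df.copy()
            df["zone"] = pd.NA
            object.__setattr__(self, "frame", df)
        zones = df["zone"].dropna()
        for bc, z in zones.items():
            comp = df.loc[bc, "compartment"]
            if z in TUMOR_ZONES:
                if comp != "tumor":
                    raise ValueError(f"zone {z} on non-tumor spot {bc}")
            elif z in GLAND_ZONES:
                if comp != "normal_gland":
                    raise ValueError(f"zone {z} on non-gland spot {bc}")
            else:
                raise ValueError(f"unknown zone label {z!r} on spot {bc}")

    @property
    def barcodes(self) -> np.ndarray:
        return self.frame.index.to_numpy(dtype=object)

    def compartment_of(self) -> pd.Series:
        return self.frame["compartment"]

    def zone_of(self) -> pd.Series:
        return self.frame["zone"]

    def barcodes_for(self, compartment: str) -> np.ndarray:
        if compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {compartment!r}; allowed: {list(COMPARTMENTS)}"
            )
        sel = self.frame["compartment"] == compartment
        return self.frame.index[sel].to_numpy(dtype=object)

    def check_covers(self, grid: SpotGrid) -> None:
        """Error unless every grid barcode is annotated (and no extras)."""
        have = set(self.frame.index)
        want = set(grid.barcodes.tolist())
        missing = want - have
        if missing:
            raise ValueError(f"annotation missing barcode {sorted(missing)[0]!r}")
        extra = have - want
        if extra:
            raise ValueError(f"annotation has unknown barcode {sorted(extra)[0]!r}")


@dataclass(frozen=True)
class CellTable:
    """Segmented cell centroids with CD44/PTN marker status.

    ``frame`` has columns cell_id, x_um, y_um, CD44_pos, PTN_pos; a
    double-positive cell has both flags true.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = ["cell_id", "x_um", "y_um", "CD44_pos", "PTN_pos"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"CellTable: missing column {col!r}")
        if df["cell_id"].duplicated().any():
            raise ValueError("CellTable: duplicate cell ids")
        coords = df[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("CellTable: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def coords(self) -> np.ndarray:
        return self.frame[["x_um", "y_um"]].to_numpy(dtype=float)

    def class_labels(self) -> pd.Series:
        """Exclusive marker-class labels: CD44+PTN+, CD44+, PTN+, other."""
        cd44 = self.frame["CD44_pos"].to_numpy(dtype=bool)
        ptn = self.frame["PTN_pos"].to_numpy(dtype=bool)
        lab = np.where(
            cd44 & ptn, "CD44+PTN+", np.where(cd44, "CD44+", np.where(ptn, "PTN+", "other"))
        )
        return pd.Series(lab, index=self.frame.index, name="class")

    def class_mask(self, cls: str, exclusive: bool = True) -> np.ndarray:
        """Boolean membership of cells in a marker class.

        With ``exclusive`` (the plotted convention) CD44+ excludes double
        positives; otherwise CD44+ means CD44_pos regardless of PTN.
        """
        cd44 = self.frame["CD44_pos"].to_numpy(dtype=bool)
        ptn = self.frame["PTN_pos"].to_numpy(dtype=bool)
        if cls == "CD44+PTN+":
            return cd44 & ptn
        if cls == "CD44+":
            return cd44 & ~ptn if exclusive else cd44
        if cls == "PTN+":
            return ptn & ~cd44 if exclusive else ptn
        if cls == "other":
            return ~cd44 & ~ptn
        raise ValueError(f"unknown cell class {cls!r}")

    def translated(self, dx_um: float, dy_um: float) -> "CellTable":
        df = self.frame.copy()
        df["x_um"] = df["x_um"] + dx_um
        df["y_um"] = df["y_um"] + dy_um
        return CellTable(df)


@dataclass(frozen=True)
class SignatureLibrary:
    """Named gene sets (e.g. the five-gene stemness panel, CAF/TAN markers)."""

    sets: Mapping[str, tuple]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("SignatureLibrary: no signatures")
        clean = {}
        for name, genes in self.sets.items():
            genes = tuple(dict.fromkeys(genes))
            if not genes:
                raise ValueError(f"signature {name!r} is empty")
            clean[str(name)] = genes
        object.__setattr__(self, "sets", clean)

    def __getitem__(self, name: str) -> tuple:
        return self.sets[name]

    def names(self) -> list:
        return list(self.sets)
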