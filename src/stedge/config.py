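"""Configuration of the synthetic-section generator.

The default configuration encodes the layered ring-like architecture the
pipeline is designed to analyse: a circular tumor compartment split into
five concentric zones (T1 innermost .. T5 the outermost rim), surrounded
by concentric normal-gland / submucosa / muscularis / lymphoid bands;
marker genes with planted radial expression gradients (CD44 rising toward
the tumor boundary, Lgr5 toward the center, CAF/TAN signature genes
confined to the rim); and tumor-cell point clouds whose CD44+/PTN+
intensity decays with distance from the boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

from .types import CELL_CLASSES, COMPARTMENTS, LATTICES

#: Five classical cancer-stem-cell marker genes.
CSC_MARKERS = ("Alcam", "Aldh2", "CD44", "Lgr5", "Prom1")

#: Signature gene sets for stromal/immune populations mapped onto spots.
ICAF_MARKERS = ("Col1a1", "Il11")
MYCAF_MARKERS = ("Pdgfrb", "Acta2")
TAN_MARKERS = ("Ly6g", "Cd101", "Cd274")

#: Histology-level compartment markers used for annotation.
COMPARTMENT_MARKERS = {
    "normal_gland": ("Krt20", "Hes1"),
    "tumor": ("Krt14", "Krt17"),
    "muscularis": ("Tpm2", "Myl9"),
    "submucosa": ("Fasn", "Fabp4"),
    "lymphoid_follicle": ("Mfge8", "Ccl21a"),
}

#: Default named signatures shipped with the generator.
DEFAULT_SIGNATURES = {
    "stemness": CSC_MARKERS,
    "iCAF": ICAF_MARKERS,
    "myCAF": MYCAF_MARKERS,
    "TAN": TAN_MARKERS,
}

# Fixed offsets deriving one RNG stream per artifact from the master seed,
# so enabling/ordering one artifact never shifts another.
_COUNTS_STREAM = 1
_CELLS_STREAM = 2


@dataclass(frozen=True)
class GradientSpec:
    """Radial modulation of a gene's mean inside the tumor.

    direction: 'edge_high' (mean rises toward the boundary),
    'center_high' (rises toward the deepest point) or 'flat'.
    amplitude is the multiplicative excess at the extreme
    (factor 1 + amplitude), decay_tau_um the exponential length scale.
    """

    direction: str
    amplitude: float
    decay_tau_um: float

    def __post_init__(self) -> None:
        if self.direction not in ("edge_high", "center_high", "flat"):
            raise ValueError(f"unknown gradient direction {self.direction!r}")
        if self.amplitude < 0:
            raise ValueError("gradient amplitude must be >= 0")
        if not self.decay_tau_um > 0:
            raise ValueError("gradient decay_tau_um must be > 0")


@dataclass(frozen=True)
class CellClassIntensity:
    """Inhomogeneous Poisson intensity lambda(d) = l0 + l1*exp(-d/tau).

    d is the distance to the tumor boundary in μm; rates are cells/mm².
    """

    lambda0_per_mm2: float
    lambda1_per_mm2: float
    decay_tau_um: float

    def __post_init__(self) -> None:
        if self.lambda0_per_mm2 < 0 or self.lambda1_per_mm2 < 0:
            raise ValueError("cell intensities must be >= 0")
        if not self.decay_tau_um > 0:
            raise ValueError("cell decay_tau_um must be > 0")


def _default_nb_mean() -> Dict[str, Dict[str, float]]:
    """Per-compartment base negative-binomial means for the default panel."""
    genes: Dict[str, Dict[str, float]] = {}

    def set_gene(gene: str, default: float, **per_comp: float) -> None:
        genes[gene] = {c: per_comp.get(c, default) for c in COMPARTMENTS}

    # background (housekeeping-like) genes, cycling over a range of depths
    bg_levels = (0.5, 1.0, 2.0, 4.0, 8.0)
    for i in range(36):
        set_gene(f"Hk{i + 1:02d}", bg_levels[i % len(bg_levels)])
    # compartment annotation markers
    for comp, markers in COMPARTMENT_MARKERS.items():
        for g in markers:
            set_gene(g, 0.5, **{comp: 8.0})
    # CSC markers expressed within the tumor
    for g in CSC_MARKERS:
        set_gene(g, 0.5, tumor=5.0)
    # CAF signature genes: stromal base + tumor-rim planting
    for g in ICAF_MARKERS + MYCAF_MARKERS:
        set_gene(g, 0.5, tumor=2.0, submucosa=2.0)
    for g in TAN_MARKERS:
        set_gene(g, 0.3, tumor=1.5)
    set_gene("Ptn", 0.5, tumor=3.0)
    # invert to compartment -> gene -> mean
    return {
        comp: {g: means[comp] for g, means in genes.items()} for comp in COMPARTMENTS
    }


def _default_gradients() -> Dict[str, GradientSpec]:
    grads = {
        "CD44": GradientSpec("edge_high", 4.0, 150.0),
        "Lgr5": GradientSpec("center_high", 4.0, 150.0),
        "Ptn": GradientSpec("edge_high", 3.0, 150.0),
    }
    for g in ICAF_MARKERS + MYCAF_MARKERS + TAN_MARKERS:
        grads[g] = GradientSpec("edge_high", 8.0, 150.0)
    return grads


def _default_cell_classes() -> Dict[str, CellClassIntensity]:
    return {
        "CD44+PTN+": CellClassIntensity(20.0, 180.0, 100.0),
        "CD44+": CellClassIntensity(30.0, 150.0, 120.0),
        # PTN single positives show no radial pattern
        "PTN+": CellClassIntensity(80.0, 0.0, 100.0),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterisation of a synthetic section.

    Identical (config, seed) pairs produce bit-identical sections.
    """

    seed: int = 0
    lattice: str = "hex"
    pitch_um: float = 100.0
    spot_diameter_um: float = 50.0
    section_extent_um: Tuple[float, float] = (4000.0, 4000.0)
    tumor_center_um: Tuple[float, float] = (2000.0, 2000.0)
    tumor_radius_um: float = 1200.0
    zone_edges_um: Tuple[float, float, float, float] = (240.0, 480.0, 720.0, 960.0)
    compartment_band_widths_um: Mapping[str, float] = field(
        default_factory=lambda: {
            "normal_gland": 400.0,
            "submucosa": 300.0,
            "muscularis": 300.0,
            "lymphoid_follicle": 200.0,
        }
    )
    nb_mean: Mapping[str, Mapping[str, float]] = field(default_factory=_default_nb_mean)
    nb_dispersion: float = 2.0
    gradient_genes: Mapping[str, GradientSpec] = field(default_factory=_default_gradients)
    cell_classes: Mapping[str, CellClassIntensity] = field(
        default_factory=_default_cell_classes
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.lattice not in LATTICES:
            raise ValueError(f"lattice must be one of {LATTICES}")
        if not self.pitch_um > 0:
            raise ValueError("pitch_um must be positive")
        if not 0 < self.spot_diameter_um <= self.pitch_um:
            raise ValueError("spot_diameter_um must be in (0, pitch_um]")
        w, h = self.section_extent_um
        if not (w > 0 and h > 0):
            raise ValueError("section_extent_um must be positive")
        if not self.tumor_radius_um > 0:
            raise ValueError("tumor_radius_um must be positive")
        edges = np.asarray(self.zone_edges_um, dtype=float)
        if edges.size != 4:
            raise ValueError("zone_edges_um must list exactly 4 radii")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("zone_edges_um must be strictly ascending")
        if not np.all(edges < self.tumor_radius_um):
            raise ValueError("zone_edges_um must all be < tumor_radius_um")
        allowed_bands = set(COMPARTMENTS) - {"tumor"}
        for name, width in self.compartment_band_widths_um.items():
            if name not in allowed_bands:
                raise ValueError(
                    f"band {name!r} not an allowed outer compartment "
                    f"({sorted(allowed_bands)})"
                )
            if not width > 0:
                raise ValueError(f"band width for {name!r} must be > 0")
        if not self.nb_dispersion > 0:
            raise ValueError("nb_dispersion must be > 0")
        gene_sets = {frozenset(m) for m in self.nb_mean.values()}
        if len(gene_sets) > 1:
            raise ValueError("nb_mean must list the same genes for every compartment")
        if set(self.nb_mean) != set(COMPARTMENTS):
            raise ValueError("nb_mean must cover all five compartments")
        genes = set(next(iter(self.nb_mean.values())))
        missing = set(self.gradient_genes) - genes
        if missing:
            raise ValueError(f"gradient genes absent from nb_mean: {sorted(missing)}")
        for comp, means in self.nb_mean.items():
            for g, m in means.items():
                if not m > 0:
                    raise ValueError(
                        f"nonpositive base mean for gene {g!r} in {comp!r}"
                    )

    @property
    def genes(self) -> list:
        return sorted(next(iter(self.nb_mean.values())))

    def counts_rng(self) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _COUNTS_STREAM])

    def cells_rng(self) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _CELLS_STREAM])

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gradient_genes"] = {
            g: dataclasses.asdict(s) for g, s in self.gradient_genes.items()
        }
        d["cell_classes"] = {
            c: dataclasses.asdict(s) for c, s in self.cell_classes.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown synthetic config key {sorted(unknown)[0]!r}")
        if "gradient_genes" in d:
            d["gradient_genes"] = {
                g: s if isinstance(s, GradientSpec) else GradientSpec(**s)
                for g, s in d["gradient_genes"].items()
            }
        if "cell_classes" in d:
            d["cell_classes"] = {
                c: s if isinstance(s, CellClassIntensity) else CellClassIntensity(**s)
                for c, s in d["cell_classes"].items()
            }
        for key in ("section_extent_um", "tumor_center_um", "zone_edges_um"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
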