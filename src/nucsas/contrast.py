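"""Scattering-length densities, contrasts, and match points.

Neutron SLDs are computed from tabulated bound coherent scattering lengths
and residue-level atom inventories (shipped in ``data/residues.json``), with
labile hydrogens exchanging against the solvent at
``exchange_fraction * fraction_d2o``.  X-ray contrasts use electron counts.
Units follow the SAS convention: neutron SLD and contrast in 1e-6 A^-2,
X-ray contrast in electrons/nm^3.

The pure-water endpoints are computed, not copied from any publication:
H2O at 1.0 g/cm^3 gives -0.56e-6 A^-2 and D2O at 1.105 g/cm^3 gives
~+6.36e-6 A^-2.  (A frequently quoted D2O value of 6.67 is the deuteron
scattering length in fm, not an SLD.)  Solvent SLD is a volume-fraction
linear mixture of the two endpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "CompositionSpec",
    "ContrastPoint",
    "ATOMS",
    "solvent_sld",
    "component_contrast",
    "component_sld",
    "theoretical_match_point",
    "xray_contrast",
    "experimental_match_point",
    "contrast_point",
    "read_composition",
]

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class Atom:
    b_coh_fm: float   # bound coherent neutron scattering length, fm
    mass: float       # atomic mass, g/mol
    electrons: int


# bound coherent scattering lengths (fm) from the standard neutron tables
ATOMS = {
    "H": Atom(-3.7390, 1.00794, 1),
    "D": Atom(6.6710, 2.01410, 1),
    "C": Atom(6.6460, 12.0107, 6),
    "N": Atom(9.3600, 14.0067, 7),
    "O": Atom(5.8030, 15.9994, 8),
    "P": Atom(5.1300, 30.97376, 15),
    "S": Atom(2.8470, 32.0650, 16),
}

DENSITY_H2O = 1.000   # g/cm^3
DENSITY_D2O = 1.105   # g/cm^3
ELECTRON_DENSITY_WATER = 334.0  # e-/nm^3

# fm/A^3 -> 1e-6 A^-2 : 1 fm = 1e-5 A, so b[fm]*1e-5 / V[A^3] in A^-2,
# i.e. *10 in units of 1e-6 A^-2
_FM_PER_A3_TO_SLD = 10.0


def _water_sld(heavy: bool) -> float:
    a_h = ATOMS["D"] if heavy else ATOMS["H"]
    a_o = ATOMS["O"]
    b = 2 * a_h.b_coh_fm + a_o.b_coh_fm
    mass = 2 * a_h.mass + a_o.mass
    density = DENSITY_D2O if heavy else DENSITY_H2O
    n_per_a3 = density * AVOGADRO / mass / 1e24
    return b * n_per_a3 * _FM_PER_A3_TO_SLD


def solvent_sld(fraction_d2o: float) -> float:
    """Neutron SLD (1e-6 A^-2) of an H2O/D2O mixture, linear in volume fraction."""
    f = float(fraction_d2o)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fraction_d2o {f} outside [0, 1]")
    return (1.0 - f) * _water_sld(False) + f * _water_sld(True)


def _load_residue_tables():
    with resources.files("nucsas.data").joinpath("residues.json").open() as fh:
        return json.load(fh)


_TABLES = _load_residue_tables()


@dataclass
class CompositionSpec:
    """Chemical composition of the protein and DNA parts of a complex.

    protein_chains : list of (sequence, copy_number)
        One-letter amino-acid sequences.
    dna_basepairs : int
        Number of base pairs; if ``dna_sequence`` (one strand, 5'->3') is
        given the complement is generated, otherwise an average 50% GC
        composition is assumed.
    exchange_fraction : float
        Fraction of labile hydrogens that exchange with solvent deuterium.
    """

    protein_chains: list = field(default_factory=list)
    dna_basepairs: int = 0
    dna_sequence: str | None = None
    exchange_fraction: float = 0.5
    mass_density_protein: float = 1.35  # g/cm^3
    mass_density_dna: float = 1.69      # g/cm^3
    partial_specific_volume: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.exchange_fraction <= 1.0:
            raise ValueError("exchange_fraction outside [0, 1]")
        if self.mass_density_protein <= 0 or self.mass_density_dna <= 0:
            raise ValueError("mass densities must be positive")
        for seq, copies in self.protein_chains:
            if copies < 1:
                raise ValueError("copy numbers must be >= 1")
            bad = set(seq.upper()) - set(_TABLES["protein"])
            if bad:
                raise ValueError(f"unknown residue code(s) {sorted(bad)}")
        if self.dna_sequence is not None:
            bad = set(self.dna_sequence.upper()) - set("ACGT")
            if bad:
                raise ValueError(f"unknown nucleotide code(s) {sorted(bad)}")

    # -- atom inventories -------------------------------------------------

    def _protein_atoms(self):
        atoms: dict = {}
        labile = 0.0
        for seq, copies in self.protein_chains:
            for res in seq.upper():
                entry = _TABLES["protein"][res]
                for el, n in entry["atoms"].items():
                    atoms[el] = atoms.get(el, 0.0) + n * copies
                labile += entry["labile_h"] * copies
            # chain termini: one extra H (amino) + OH (carboxyl), both labile
            atoms["H"] = atoms.get("H", 0.0) + 2 * copies
            atoms["O"] = atoms.get("O", 0.0) + 1 * copies
            labile += 2 * copies
        return atoms, labile

    def _dna_atoms(self):
        atoms: dict = {}
        labile = 0.0
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        if self.dna_sequence is not None:
            strands = self.dna_sequence.upper()
            counts: dict = {}
            for nt in strands:
                counts[nt] = counts.get(nt, 0) + 1
                counts[comp[nt]] = counts.get(comp[nt], 0) + 1
        else:
            # average composition, 50% GC: n_bp of each A/T and G/C pair halves
            n = float(self.dna_basepairs)
            counts = {"A": n / 2, "T": n / 2, "G": n / 2, "C": n / 2}
        for nt, n in counts.items():
            entry = _TABLES["dna"][nt]
            for el, cnt in entry["atoms"].items():
                atoms[el] = atoms.get(el, 0.0) + cnt * n
            labile += entry["labile_h"] * n
        return atoms, labile

    def _atoms(self, component: str):
        if component == "protein":
            atoms, labile = self._protein_atoms()
        elif component == "dna":
            atoms, labile = self._dna_atoms()
        else:
            raise ValueError(f"unknown component {component!r}")
        if not atoms:
            raise ValueError(f"empty {component} component")
        return atoms, labile

    def molecular_weight(self, component: str) -> float:
        """Protonated molecular weight (g/mol) of a component."""
        atoms, _ = self._atoms(component)
        return sum(ATOMS[el].mass * n for el, n in atoms.items())

    def volume(self, component: str) -> float:
        """Dry volume (A^3) of a component from its mass density."""
        density = (
            self.mass_density_protein if component == "protein" else self.mass_density_dna
        )
        return self.molecular_weight(component) / density / AVOGADRO * 1e24

    def scattering_length(self, component: str, fraction_d2o: float) -> float:
        """Total coherent scattering length (fm) with labile H/D exchange."""
        atoms, labile = self._atoms(component)
        b = sum(ATOMS[el].b_coh_fm * n for el, n in atoms.items())
        x = self.exchange_fraction * float(fraction_d2o)
        b += labile * x * (ATOMS["D"].b_coh_fm - ATOMS["H"].b_coh_fm)
        return b

    def electrons(self, component: str) -> float:
        atoms, _ = self._atoms(component)
        return sum(ATOMS[el].electrons * n for el, n in atoms.items())


@dataclass
class ContrastPoint:
    """Contrasts (1e-6 A^-2) of both components at one D2O fraction."""

    fraction_d2o: float
    rho_solvent: float
    delta_rho_protein: float
    delta_rho_dna: float
    delta_rho_complex: float


def component_sld(comp: CompositionSpec, component: str, fraction_d2o: float) -> float:
    """Neutron SLD (1e-6 A^-2) of a component at the given D2O fraction."""
    b = comp.scattering_length(component, fraction_d2o)
    v = comp.volume(component)
    return b / v * _FM_PER_A3_TO_SLD  # fm/A^3 -> 1e-6 A^-2


def component_contrast(comp: CompositionSpec, component: str, fraction_d2o: float) -> float:
    """Contrast Delta-rho = rho_component - rho_solvent, in 1e-6 A^-2."""
    return component_sld(comp, component, fraction_d2o) - solvent_sld(fraction_d2o)


def contrast_point(comp: CompositionSpec, fraction_d2o: float) -> ContrastPoint:
    """All contrasts at one D2O fraction; complex = volume-weighted mean."""
    dp = component_contrast(comp, "protein", fraction_d2o)
    dd = component_contrast(comp, "dna", fraction_d2o)
    vp, vd = comp.volume("protein"), comp.volume("dna")
    dc = (vp * dp + vd * dd) / (vp + vd)
    return ContrastPoint(
        fraction_d2o=float(fraction_d2o),
        rho_solvent=solvent_sld(fraction_d2o),
        delta_rho_protein=dp,
        delta_rho_dna=dd,
        delta_rho_complex=dc,
    )


def theoretical_match_point(comp: CompositionSpec, component: str = "complex") -> float:
    """D2O fraction at which the component's contrast vanishes.

    The contrast is linear in fraction_d2o, so the match point is the root
    of the line through the fD2O = 0 and 1 endpoints.
    """
    if component == "complex":
        c0 = contrast_point(comp, 0.0).delta_rho_complex
        c1 = contrast_point(comp, 1.0).delta_rho_complex
    else:
        c0 = component_contrast(comp, component, 0.0)
        c1 = component_contrast(comp, component, 1.0)
    if c0 * c1 >= 0:
        raise ValueError(
            f"{component} contrast does not change sign on [0, 1] "
            f"({c0:.3g} to {c1:.3g}); no match point"
        )
    return c0 / (c0 - c1)


def xray_contrast(comp: CompositionSpec, component: str) -> float:
    """X-ray electron-density contrast vs water, in e-/nm^3."""
    n_e = comp.electrons(component)
    v_nm3 = comp.volume(component) * 1e-3  # A^3 -> nm^3
    if v_nm3 <= 0:
        raise ValueError("zero component volume")
    return n_e / v_nm3 - ELECTRON_DENSITY_WATER


@dataclass
class MatchPointFit:
    match_point: float
    match_point_sigma: float
    slope: float
    intercept: float
    ambiguous: bool
    signs: np.ndarray
    residuals: np.ndarray


def experimental_match_point(points, sigmas=None) -> MatchPointFit:
    """Match point from sqrt(I0/c) vs D2O fraction.

    ``points`` is a sequence of (fraction_d2o, i0, concentration).  The
    square root loses the sign of the contrast, so signs are re-assigned:
    every split of the fraction-sorted sequence into a leading (+) and
    trailing (-) block is tried and the weighted-least-squares best line
    kept.  The x-intercept is the match point; its uncertainty comes from
    the fit covariance.  If the signed sequence has no significant trend
    (|slope| < 2 sigma_slope) the result is flagged ambiguous.
    """
    pts = sorted((float(f), float(i0), float(c)) for f, i0, c in points)
    if len(pts) < 2:
        raise ValueError("need >= 2 contrast points")
    f = np.array([p[0] for p in pts])
    if np.unique(f).size < 2:
        raise ValueError("all fractions identical; fit is degenerate")
    y_abs = np.array([np.sqrt(p[1] / p[2]) for p in pts])
    if sigmas is None:
        w = np.ones_like(y_abs)
    else:
        w = 1.0 / np.asarray(sigmas, dtype=float)

    best = None
    n = len(pts)
    for split in range(n + 1):
        signs = np.where(np.arange(n) < split, 1.0, -1.0)
        for flip in (1.0, -1.0):
            y = flip * signs * y_abs
            A = np.column_stack([f, np.ones_like(f)]) * w[:, None]
            coef, res, *_ = np.linalg.lstsq(A, y * w, rcond=None)
            ssr = float(np.sum((A @ coef - y * w) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, coef, flip * signs, y)
    ssr, (m, b), signs, y = best
    if m == 0:
        raise ValueError("zero slope; no match point")
    dof = max(n - 2, 1)
    cov = np.linalg.inv((np.column_stack([f, np.ones_like(f)]) * w[:, None]).T
                        @ (np.column_stack([f, np.ones_like(f)]) * w[:, None]))
    cov = cov * ssr / dof if ssr > 0 else cov * 0.0
    mp = -b / m
    # var(-b/m) by first-order propagation
    g = np.array([b / m**2, -1.0 / m])
    mp_sigma = float(np.sqrt(g @ cov @ g))
    slope_sigma = float(np.sqrt(cov[0, 0]))
    ambiguous = slope_sigma > 0 and abs(m) < 2 * slope_sigma
    residuals = y - (m * f + b)
    return MatchPointFit(mp, mp_sigma, float(m), float(b), bool(ambiguous), signs, residuals)


def read_composition(path) -> CompositionSpec:
    """Read a composition from a small structured text file.

    Lines: ``protein <copies> <sequence>``, ``dna_bp <n>``,
    ``dna_seq <sequence>``, ``exchange <frac>``, ``density_protein <d>``,
    ``density_dna <d>``.  '#' comments allowed.  FASTA protein files can
    be inlined by one ``protein`` line per chain.
    """
    chains = []
    kwargs: dict = {}
    from pathlib import Path

    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        key = parts[0].lower()
        if key == "protein":
            chains.append((parts[2], int(parts[1])))
        elif key == "dna_bp":
            kwargs["dna_basepairs"] = int(parts[1])
        elif key == "dna_seq":
            kwargs["dna_sequence"] = parts[1]
            kwargs.setdefault("dna_basepairs", len(parts[1]))
        elif key == "exchange":
            kwargs["exchange_fraction"] = float(parts[1])
        elif key == "density_protein":
            kwargs["mass_density_protein"] = float(parts[1])
        elif key == "density_dna":
            kwargs["mass_density_dna"] = float(parts[1])
        else:
            raise ValueError(f"unknown composition key {key!r}")
    return CompositionSpec(protein_chains=chains, **kwargs)
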