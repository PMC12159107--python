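"""Multi-contrast inference: Stuhrmann analysis, component molecular
weights from forward intensities, and per-q decomposition of a contrast
series into protein, DNA, and cross-term intensities.

The contrast-variation decomposition used throughout is

    I(q) = dP^2 I_P(q) + dP dD I_PD(q) + dD^2 I_D(q)

with dP/dD the protein/DNA contrasts of each measurement.  (The physically
standard form with dD^2 on the DNA term is used.)  Component molecular
weights follow the absolute-scale relation

    sqrt(I0/n) = |dP| MW_P / (Na dP_mass) + |dD| MW_D / (Na dD_mass)

with n the particle number density, solved by weighted least squares and
iterated to self-consistency in the total mass entering n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contrast import AVOGADRO, CompositionSpec, contrast_point
from .profiles import ScatteringProfile

__all__ = [
    "StuhrmannFit",
    "ComponentMW",
    "ComponentIntensities",
    "stuhrmann_fit",
    "component_molecular_weights",
    "decompose_component_intensities",
]


# ---------------------------------------------------------------------------
# Stuhrmann analysis
# ---------------------------------------------------------------------------

@dataclass
class StuhrmannFit:
    """Fit of Rg^2 = Rc^2 + alpha/drho - beta/drho^2.

    rc is the radius of gyration at infinite contrast (the shape term);
    alpha > 0 places the higher-SLD component peripherally; beta != 0
    means the component centres of scattering mass are displaced.
    Units: rc A; alpha A^2 * (1e-6 A^-2); beta A^2 * (1e-6 A^-2)^2.
    """

    rc: float
    rc_sigma: float
    alpha: float
    alpha_sigma: float
    beta: float
    beta_sigma: float
    fit_points: list
    model: str
    ill_conditioned: bool = False


def stuhrmann_fit(points, model: str = "hyperbolic", weighted: bool = True) -> StuhrmannFit:
    """Weighted least squares of Rg^2 on (1, 1/drho, -1/drho^2).

    ``points``: sequence of (delta_rho, rg, sigma_rg), delta_rho in
    1e-6 A^-2 and nonzero.  ``model='linear'`` drops the beta term.
    sigma_rg propagates to sigma on Rg^2 as 2 rg sigma_rg; ``weighted=False``
    fits all points equally (plot-space convention of manual fits).
    The design is flagged ill-conditioned when the 1/drho values are too
    clustered to separate the terms.
    """
    pts = [(float(d), float(r), float(s)) for d, r, s in points]
    if any(d == 0 for d, _, _ in pts):
        raise ValueError("delta_rho must be nonzero")
    n_par = 3 if model == "hyperbolic" else 2
    if model not in ("hyperbolic", "linear"):
        raise ValueError(f"unknown model {model!r}")
    if len(pts) < n_par:
        raise ValueError(f"{model} Stuhrmann fit needs >= {n_par} points")
    x = np.array([1.0 / d for d, _, _ in pts])
    y = np.array([r**2 for _, r, _ in pts])
    sy = np.array([2.0 * r * s for _, r, s in pts])
    if weighted and np.all(sy > 0):
        w = 1.0 / sy
    else:
        w = np.ones_like(y)
    cols = [np.ones_like(x), x]
    if n_par == 3:
        cols.append(-(x**2))
    X = np.column_stack(cols)
    Aw = X * w[:, None]
    yw = y * w
    coef, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
    resid = yw - Aw @ coef
    dof = max(len(pts) - n_par, 1)
    s2 = float(resid @ resid) / dof
    cov = np.linalg.pinv(Aw.T @ Aw)
    if len(pts) > n_par:
        cov = cov * max(s2, 1.0)  # scale up only; keep prior sigmas as floor
    cond = np.linalg.cond(Aw)
    ill = bool(cond > 1e8 or np.ptp(np.abs(x)) < 1e-3 * np.max(np.abs(x)))
    rc2 = coef[0]
    if rc2 <= 0:
        raise ValueError("fitted Rc^2 is non-positive")
    rc = math.sqrt(rc2)
    rc_sigma = math.sqrt(cov[0, 0]) / (2.0 * rc)
    alpha = float(coef[1])
    alpha_sigma = math.sqrt(cov[1, 1])
    if n_par == 3:
        beta, beta_sigma = float(coef[2]), math.sqrt(cov[2, 2])
    else:
        beta, beta_sigma = 0.0, 0.0
    return StuhrmannFit(rc, rc_sigma, alpha, alpha_sigma, beta, beta_sigma,
                        pts, model, ill)


# ---------------------------------------------------------------------------
# Component molecular weights
# ---------------------------------------------------------------------------

@dataclass
class ComponentMW:
    mw_protein: float
    mw_protein_sigma: float
    mw_dna: float
    mw_dna_sigma: float
    mw_total: float
    negative_flag: bool = False


def component_molecular_weights(
    points,
    comp: CompositionSpec,
    mw_total_guess: float | None = None,
    iterate: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ComponentMW:
    """Solve component molecular weights from absolute-scale I0 values.

    ``points``: sequence of (fraction_d2o, i0_abs [cm^-1], concentration
    [mg/mL]) at >= 2 distinct D2O fractions.  The number density
    n = c Na / MW_total depends on the unknown total mass, so by default
    the 2x2 weighted solve is iterated to self-consistency (it converges
    in a few steps because sqrt(I0/n) scales as sqrt(MW_total)).  With
    ``iterate=False`` the number density stays fixed at the provisional
    total mass (the composition's, or ``mw_total_guess``); in that mode
    the solve is exactly linear in sqrt(I0).

    A negative solved mass is reported with ``negative_flag`` set, never
    silently clamped.
    """
    pts = [(float(f), float(i0), float(c)) for f, i0, c in points]
    if len(pts) < 2:
        raise ValueError("need >= 2 contrast points")
    fracs = [p[0] for p in pts]
    if len(set(fracs)) < 2:
        raise ValueError("contrast points must have distinct D2O fractions")
    if any(i0 <= 0 or c <= 0 for _, i0, c in pts):
        raise ValueError("I0 and concentration must be positive")

    # contrast coefficients per point, in cm^-2 (1e-6 A^-2 = 1e10 cm^-2)
    A = np.empty((len(pts), 2))
    for k, (f, _, _) in enumerate(pts):
        cp = contrast_point(comp, f)
        A[k, 0] = abs(cp.delta_rho_protein) * 1e10 / (AVOGADRO * comp.mass_density_protein)
        A[k, 1] = abs(cp.delta_rho_dna) * 1e10 / (AVOGADRO * comp.mass_density_dna)
    if np.linalg.matrix_rank(A, tol=1e-12 * np.abs(A).max()) < 2:
        raise ValueError("contrast coefficient vectors are collinear; degenerate")

    mw_total = mw_total_guess or (
        comp.molecular_weight("protein") + comp.molecular_weight("dna")
    ) or 2.0e5
    i0 = np.array([p[1] for p in pts])
    conc = np.array([p[2] * 1e-3 for p in pts])  # g/cm^3
    cov = np.eye(2)
    for _ in range(max_iter if iterate else 1):
        n = conc * AVOGADRO / mw_total  # particles/cm^3
        y = np.sqrt(i0 / n)             # cm
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        cov = np.linalg.pinv(A.T @ A)
        new_total = float(sol[0] + sol[1])
        if not iterate or new_total <= 0:
            break
        if abs(new_total - mw_total) <= tol * abs(mw_total):
            mw_total = new_total
            break
        mw_total = new_total
    resid = A @ sol - y
    dof = max(len(pts) - 2, 1)
    s2 = float(resid @ resid) / dof
    sig = np.sqrt(np.diag(cov) * max(s2, 0.0))
    neg = bool(sol[0] < 0 or sol[1] < 0)
    return ComponentMW(float(sol[0]), float(sig[0]), float(sol[1]), float(sig[1]),
                       float(sol[0] + sol[1]), neg)


# ---------------------------------------------------------------------------
# Per-q component decomposition
# ---------------------------------------------------------------------------

@dataclass
class ComponentIntensities:
    q: np.ndarray
    i_protein: np.ndarray
    i_dna: np.ndarray
    i_cross: np.ndarray
    covariance: np.ndarray  # (nq, 3, 3) ordered (I_P, I_PD, I_D)

    def reconstruct(self, delta_rho_protein: float, delta_rho_dna: float) -> np.ndarray:
        """I(q) at an arbitrary contrast from the decomposed components."""
        return (delta_rho_protein**2 * self.i_protein
                + delta_rho_protein * delta_rho_dna * self.i_cross
                + delta_rho_dna**2 * self.i_dna)


def decompose_component_intensities(
    series,
    comp: CompositionSpec | None = None,
    contrasts=None,
    fit_background: bool = False,
) -> ComponentIntensities:
    """Per-q weighted solve for I_P(q), I_PD(q), I_D(q).

    ``series``: >= 3 ScatteringProfiles at distinct D2O fractions.  The
    contrasts (dP, dD) per profile come from ``contrasts`` (sequence of
    pairs, 1e-6 A^-2) or are computed from ``comp`` and each profile's
    ``meta['fraction_d2o']``.  Profiles are interpolated onto the q grid of
    the first profile restricted to the common range.  With
    ``fit_background`` a flat per-profile nuisance term is included
    (incoherent background not subtracted upstream).
    """
    series = list(series)
    if len(series) < 3:
        raise ValueError("need >= 3 profiles at distinct contrasts")
    if contrasts is None:
        if comp is None:
            raise ValueError("provide comp or explicit contrasts")
        contrasts = []
        for p in series:
            f = p.meta.get("fraction_d2o")
            if f is None:
                raise ValueError("profile missing fraction_d2o metadata")
            cp = contrast_point(comp, f)
            contrasts.append((cp.delta_rho_protein, cp.delta_rho_dna))
    contrasts = [(float(a), float(b)) for a, b in contrasts]
    if len({round(a, 9) for a, _ in contrasts}) < 3:
        raise ValueError("need >= 3 distinct contrasts")

    qlo = max(p.q[0] for p in series)
    qhi = min(p.q[-1] for p in series)
    if qhi <= qlo:
        raise ValueError("profiles share no q range")
    q = series[0].q[(series[0].q >= qlo) & (series[0].q <= qhi)]
    nq = q.size
    nc = len(series)
    I = np.empty((nc, nq))
    S = np.empty((nc, nq))
    for k, p in enumerate(series):
        I[k] = np.interp(q, p.q, p.intensity)
        S[k] = np.interp(q, p.q, p.sigma)

    n_par = 3 + (nc if fit_background else 0)
    base = np.zeros((nc, n_par))
    for k, (dp, dd) in enumerate(contrasts):
        base[k, :3] = (dp**2, dp * dd, dd**2)
        if fit_background:
            base[k, 3 + k] = 1.0
    if np.linalg.matrix_rank(base[:, :3]) < 3:
        raise ValueError("singular contrast design; fractions too clustered")

    i_p = np.empty(nq)
    i_pd = np.empty(nq)
    i_d = np.empty(nq)
    cov = np.empty((nq, 3, 3))
    for j in range(nq):
        w = 1.0 / S[:, j]
        Aw = base * w[:, None]
        yw = I[:, j] * w
        sol, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
        cj = np.linalg.pinv(Aw.T @ Aw)
        i_p[j], i_pd[j], i_d[j] = sol[0], sol[1], sol[2]
        cov[j] = cj[:3, :3]
    return ComponentIntensities(q, i_p, i_d, i_pd, cov)
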