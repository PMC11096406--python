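"""Veronda-Westmann hyperelastic law and least-squares parameter estimation.

The Veronda-Westmann model is an isotropic, incompressible hyperelastic law
originally proposed for skin.  Its strain energy density is

    Psi(I1b, I2b) = (mu/gamma) * (exp(gamma*(I1b - 3)) - 1) - mu * (I2b - 3)

with stiffness scale ``mu`` (MPa) and strain-stiffening exponent ``gamma``
(dimensionless).  Under incompressible uniaxial kinematics with principal
stretch ``lam = 1 + eps_N`` the deviatoric invariants are

    I1b = lam**2 + 2/lam        I2b = 2*lam + 1/lam**2

and the nominal (first Piola-Kirchhoff) stress along the loading axis is

    sigma_N = 2*mu*(1 - lam**-3) * (lam*exp(gamma*(I1b - 3)) - 1)

which is the derivative of Psi with respect to lam.  At ``gamma = 0`` the
energy degenerates to the analytic series limit ``mu*(I1b - I2b)`` and the
stress to ``2*mu*(1 - lam**-3)*(lam - 1)``; both are handled without a 0/0
division.  Note this parameterization has zero initial tangent modulus:
the small-strain expansion is ``sigma_N = 6*mu*eps**2 + O(eps**3)``, a
toe-region flatness typical of reported skin stress-strain curves.

Parameters are estimated from a nominal stress-strain curve by unweighted
nonlinear least squares with an analytic Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "UniaxialKinematics",
    "VWParameters",
    "VWFit",
    "HyperelasticLaw",
    "VerondaWestmann",
    "VERONDA_WESTMANN",
    "kinematics",
    "strain_energy",
    "nominal_stress",
    "fit_law",
    "fit_vw",
]

# bounds chosen so the search space comfortably covers reported skin values:
# mu quartiles O(0.1-1) MPa, gamma quartiles O(0.01-0.1); gamma < 0 destroys
# convexity of the exponential term and is excluded.
MU_BOUNDS = (1e-6, 1e3)
GAMMA_BOUNDS = (0.0, 50.0)
_GAMMA0 = 0.05

# cap on the stiffening exponent gamma*(I1b - 3): exp() of anything larger
# overflows float64, so the cap only replaces inf with ~1e304
_EXP_CAP = 700.0


@dataclass(frozen=True)
class UniaxialKinematics:
    """Principal stretch and deviatoric invariants of uniaxial extension.

    All fields may be scalars or equally shaped arrays.  Both invariants
    equal 3 exactly in the reference configuration (stretch 1).
    """

    stretch: np.ndarray
    i1_bar: np.ndarray
    i2_bar: np.ndarray


@dataclass(frozen=True)
class VWParameters:
    """Veronda-Westmann material coefficients: mu (MPa, > 0), gamma (>= 0)."""

    mu: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise ValueError(f"mu must be positive, got {self.mu}")
        if not (self.gamma >= 0):
            raise ValueError(f"gamma must be nonnegative, got {self.gamma}")


@dataclass(frozen=True)
class VWFit:
    """Result of fitting the Veronda-Westmann law to one specimen curve.

    ``r_squared`` is the coefficient of determination on nominal stress,
    ``residual_norm`` the Euclidean norm of the stress residuals (MPa) and
    ``energy_at_peak`` the strain energy density Psi (MPa) evaluated at the
    fitted parameters and the largest stretch on the fitted curve.
    """

    params: VWParameters
    r_squared: float
    residual_norm: float
    converged: bool
    energy_at_peak: float


def kinematics(strain) -> UniaxialKinematics:
    """Map nominal strain to stretch and deviatoric invariants.

    Parameters
    ----------
    strain
        Nominal strain eps_N, scalar or array; must satisfy eps_N > -1.
    """
    eps = np.asarray(strain, dtype=float)
    if np.any(eps <= -1):
        raise ValueError("nominal strain must exceed -1 (stretch must be positive)")
    lam = 1.0 + eps
    return UniaxialKinematics(
        stretch=lam,
        i1_bar=lam**2 + 2.0 / lam,
        i2_bar=2.0 * lam + lam**-2,
    )


def strain_energy(kin: UniaxialKinematics, params: VWParameters):
    """Strain energy density Psi (MPa) at the given kinematic state.

    The gamma -> 0 limit mu*(I1b - I2b) is returned analytically (via expm1
    at small gamma the formula is numerically stable anyway; gamma == 0 is
    special-cased to avoid the 0/0 form).
    """
    x = kin.i1_bar - 3.0
    if params.gamma == 0.0:
        exp_term = params.mu * x
    else:
        exp_term = (params.mu / params.gamma) * np.expm1(
            np.minimum(params.gamma * x, _EXP_CAP)
        )
    return exp_term - params.mu * (kin.i2_bar - 3.0)


def nominal_stress(kin: UniaxialKinematics, params: VWParameters):
    """Uniaxial nominal stress sigma_N (MPa) = dPsi/dlam.

    sigma_N = 2*mu*(1 - lam**-3) * (lam*exp(gamma*(I1b - 3)) - 1); the
    expression is regular at gamma = 0 and vanishes at lam = 1 for all
    parameters.
    """
    lam = kin.stretch
    return 2.0 * params.mu * (1.0 - lam**-3) * (
        lam * np.exp(np.minimum(params.gamma * (kin.i1_bar - 3.0), _EXP_CAP)) - 1.0
    )


# ---------------------------------------------------------------------------
# plugin seam for alternative hyperelastic laws


class HyperelasticLaw:
    """Interface an alternative uniaxial hyperelastic law must provide.

    Subclasses supply a name, parameter names and bounds, a stress function
    on nominal strain, and an initial guess from a curve; ``fit_law`` then
    estimates the parameters by the same least-squares procedure used for
    the Veronda-Westmann default.
    """

    name: str = "base"
    param_names: Sequence[str] = ()
    lower: Sequence[float] = ()
    upper: Sequence[float] = ()

    def stress(self, strain: np.ndarray, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def jacobian(self, strain: np.ndarray, theta: np.ndarray) -> np.ndarray | None:
        """d sigma / d theta, shape (n_points, n_params); None -> numeric."""
        return None

    def initial_guess(self, strain: np.ndarray, stress: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _initial_secant_modulus(strain: np.ndarray, stress: np.ndarray) -> float:
    """Secant slope of the curve over the first 10% of its strain range."""
    lo = strain > 0
    cutoff = 0.1 * strain.max()
    mask = lo & (strain <= cutoff)
    if mask.sum() < 1:
        mask = lo  # very coarse curves: fall back to the whole range
    i = np.flatnonzero(mask)[-1]
    return float(stress[i] / strain[i]) if strain[i] > 0 else 1.0


class VerondaWestmann(HyperelasticLaw):
    """Default law: theta = (mu, gamma)."""

    name = "veronda-westmann"
    param_names = ("mu", "gamma")
    lower = (MU_BOUNDS[0], GAMMA_BOUNDS[0])
    upper = (MU_BOUNDS[1], GAMMA_BOUNDS[1])

    def stress(self, strain, theta):
        return nominal_stress(kinematics(strain), VWParameters(max(theta[0], MU_BOUNDS[0]), max(theta[1], 0.0)))

    def jacobian(self, strain, theta):
        mu, gamma = theta
        kin = kinematics(strain)
        lam = kin.stretch
        x = kin.i1_bar - 3.0
        pref = 2.0 * (1.0 - lam**-3)
        e = np.exp(np.minimum(gamma * x, _EXP_CAP))
        d_mu = pref * (lam * e - 1.0)
        d_gamma = 2.0 * mu * (1.0 - lam**-3) * lam * e * x
        return np.column_stack([d_mu, d_gamma])

    def initial_guess(self, strain, stress):
        # the initial secant slope over-estimates 6*mu*eps (quadratic toe),
        # which still lands mu0 within the trust region of every curve the
        # generator produces; gamma starts at a mildly stiffening value
        mu0 = _initial_secant_modulus(strain, stress) / 6.0
        mu0 = float(np.clip(mu0, MU_BOUNDS[0] * 10, MU_BOUNDS[1] / 10))
        return np.array([mu0, _GAMMA0])


VERONDA_WESTMANN = VerondaWestmann()


def fit_law(strain, stress, law: HyperelasticLaw):
    """Bounded least-squares fit of an arbitrary uniaxial hyperelastic law.

    Returns ``(theta, r_squared, residual_norm, converged)``.  The objective
    is the unweighted sum of squared nominal-stress residuals; the law's
    analytic Jacobian is used when provided, otherwise finite differences.
    """
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    if strain.size < 5:
        raise ValueError(f"need at least 5 points to fit, got {strain.size}")

    theta0 = law.initial_guess(strain, stress)

    # a uniform residual scale keeps the cost finite on extreme curves
    # without moving the minimizer (R^2 is scale-invariant); the hard clip
    # only guards float overflow far outside any plausible optimum
    s = max(1.0, float(np.max(np.abs(stress))))
    _CLIP = 1e100

    def resid(theta):
        return np.clip((law.stress(strain, theta) - stress) / s, -_CLIP, _CLIP)

    jac = "2-point"
    if law.jacobian(strain, theta0) is not None:
        jac = lambda theta: np.clip(  # noqa: E731
            law.jacobian(strain, theta) / s, -_CLIP, _CLIP
        )

    sol = least_squares(
        resid, theta0, jac=jac, bounds=(list(law.lower), list(law.upper)),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    stress_s = stress / s
    fitted_s = law.stress(strain, sol.x) / s
    ss_res = float(np.sum((fitted_s - stress_s) ** 2))
    ss_tot = float(np.sum((stress_s - stress_s.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return sol.x, r2, float(np.sqrt(ss_res) * s), bool(sol.success)


def fit_vw(curve) -> VWFit:
    """Estimate Veronda-Westmann parameters from a stress-strain curve.

    The curve should already be truncated at its failure peak and have at
    least 5 points.  Deterministic given the curve.

    Returns
    -------
    VWFit
        Fitted (mu, gamma) with R^2 on nominal stress, residual norm,
        convergence flag and the strain energy at the curve's peak stretch.
    """
    theta, r2, rnorm, ok = fit_law(curve.strain, curve.stress, VERONDA_WESTMANN)
    params = VWParameters(mu=float(theta[0]), gamma=float(theta[1]))
    peak_kin = kinematics(float(np.asarray(curve.strain).max()))
    return VWFit(
        params=params,
        r_squared=r2,
        residual_norm=rnorm,
        converged=ok,
        energy_at_peak=float(strain_energy(peak_kin, params)),
    )
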