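"""Monte Carlo and analytic propagation of efflux uncertainties.

Per iteration the stratum-mean fluxes and surface areas are perturbed and the
stratified sums recomputed. Independence structure: the six regions and the
water types (streams/rivers vs lakes/reservoirs) are treated as statistically
independent; strata *within* a region share a single standard-normal draw for
their flux means (they derive from the same regional site population), while
areas are perturbed independently per cell with zero-truncated normals.
Summaries are the mean, SD and the 5th/95th percentiles of the iterate
distribution. Point estimates with independent errors combine analytically as
value = sum, sd = sqrt(sum of squares).
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .upscale import EffluxEstimate, MG_C_PER_MMOL_CO2, MG_PER_TG, integrate_efflux
from .hydrography import SurfaceInventory

DEFAULT_ITERATIONS = 10_000
PCTL_LOW, PCTL_HIGH = 5.0, 95.0


def monte_carlo_efflux(
    fluxes,
    areas: SurfaceInventory,
    ice_free_days: Mapping[str, Mapping[str, float]],
    n_iter: int = DEFAULT_ITERATIONS,
    seed: int | np.random.SeedSequence | None = 0,
    area_rel_sd: float = 0.0,
    scope: tuple = (),
) -> EffluxEstimate:
    """Monte Carlo efflux distribution for one water type.

    ``fluxes`` is a stratum-flux table (see upscale); its ``sd_F`` column sets
    the per-cell flux SD. ``area_rel_sd`` applies one relative SD to every
    inventory cell (the inventory-wide delineation uncertainty). Reproducible
    for a fixed seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if n_iter < 100:
        warnings.warn("n_iter < 100: 5th/95th percentiles will be unstable", stacklevel=2)

    cells = integrate_efflux(fluxes, areas, ice_free_days)
    mean_F = cells["mean_F"].to_numpy()
    sd_F = cells["sd_F"].to_numpy()
    area = cells["area_m2"].to_numpy()
    days = cells["days"].to_numpy()

    rng = np.random.default_rng(seed)
    regions = cells["region"].to_numpy()
    region_codes, region_idx = np.unique(regions, return_inverse=True)

    # shared per-region draw for flux means, clipped at zero
    z = rng.standard_normal((n_iter, len(region_codes)))
    F_draw = np.clip(mean_F[None, :] + z[:, region_idx] * sd_F[None, :], 0.0, None)

    if area_rel_sd > 0.0:
        a = -1.0 / area_rel_sd  # truncation at zero in standard units
        t = stats.truncnorm.rvs(
            a, np.inf, size=(n_iter, len(area)), random_state=np.random.default_rng(rng.integers(2**31))
        )
        A_draw = area[None, :] * (1.0 + area_rel_sd * t)
    else:
        A_draw = area[None, :]

    totals = (F_draw * A_draw * days[None, :] * MG_C_PER_MMOL_CO2 / MG_PER_TG).sum(axis=1)
    lo, hi = np.percentile(totals, [PCTL_LOW, PCTL_HIGH])
    return EffluxEstimate(
        value=float(totals.mean()),
        sd=float(totals.std(ddof=1)) if n_iter > 1 else 0.0,
        ci5=float(lo),
        ci95=float(hi),
        scope=scope,
    )


def combine_independent(estimates: Iterable[EffluxEstimate], scope: tuple = ()) -> EffluxEstimate:
    """Sum independent efflux components: values add, SDs add in quadrature.

    The combined 5th/95th interval uses the normal approximation
    value -/+ 1.645 sd (component-level percentile draws are not retained).
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("need at least one estimate")
    value = sum(e.value for e in estimates)
    sd = math.sqrt(sum(e.sd**2 for e in estimates))
    z90 = stats.norm.ppf(0.95)
    return EffluxEstimate(
        value=value, sd=sd, ci5=value - z90 * sd, ci95=value + z90 * sd, scope=scope
    )
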