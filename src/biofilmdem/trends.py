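"""Desk-scale reproduction workflows.

Each function runs replicated scaled-preset simulations and returns tidy
summary tables: the nutrient-condition morphology grid, the feed-direction
comparison, growth under shear, and shear-driven erosion of a pre-grown
film.  They are the programmatic counterpart of the CLI and are used by
the acceptance machinery; problem sizes are those of the scaled presets
(see docs/methods.md).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .analysis import height_field, morphology, occupancy
from .scenarios import (DETACH_SHEAR_RATES, TREND_DELTA_KAPPA,
                        TREND_SHEAR_RATES, Scenario, preset, run)

__all__ = ["ribbon_morphology", "growth_grid_trend", "feed_comparison",
           "shear_growth_trend", "detachment_trend"]

_RIBBON_COLUMNS = (24, 1)   # height-field columns for the 40x4 um ribbon


def ribbon_morphology(series):
    """Morphology of a final ribbon-domain state (fine x columns)."""
    a = series.final
    p = series.params.internal()
    h = height_field(a, series.domain, p, grid=_RIBBON_COLUMNS)
    return morphology(h, occupancy(a, series.domain, p), series.domain)


def _seed(base_seed: int, k: int) -> int:
    return (base_seed * 1000 + k) % (2**31 - 1)


def growth_grid_trend(replicates: int = 5, base_seed: int = 1,
                      grid=TREND_DELTA_KAPPA) -> pd.DataFrame:
    """Quiescent growth across the increasing (delta, kappa) grid."""
    rows = []
    for delta, kappa in grid:
        params, domain, scen = preset("growth_grid_scaled",
                                      delta=delta, kappa=kappa)
        for rep in range(replicates):
            s = run(params, domain, scen, seed=_seed(base_seed, rep))
            m = ribbon_morphology(s)
            rows.append({"delta": delta, "kappa": kappa, "replicate": rep,
                         "roughness": m.roughness, "porosity": m.porosity,
                         "mean_height": m.mean_height,
                         "max_height": m.max_height,
                         "tstar": s.metrics.tstar.iloc[-1],
                         "n_agents": s.final.n})
    return pd.DataFrame(rows)


def feed_comparison(replicates: int = 5, base_seed: int = 1,
                    delta: float | None = None,
                    kappa: float | None = None) -> pd.DataFrame:
    """Top- vs bottom-fed nutrient supply at the lowest (delta, kappa)."""
    d0, k0 = TREND_DELTA_KAPPA[0]
    delta = d0 if delta is None else delta
    kappa = k0 if kappa is None else kappa
    rows = []
    for feed in ("top", "bottom"):
        params, domain, scen = preset("growth_grid_scaled", delta=delta,
                                      kappa=kappa, feed=feed)
        for rep in range(replicates):
            s = run(params, domain, scen, seed=_seed(base_seed, rep))
            m = ribbon_morphology(s)
            rows.append({"feed": feed, "replicate": rep,
                         "roughness": m.roughness, "porosity": m.porosity})
    return pd.DataFrame(rows)


def shear_growth_trend(replicates: int = 5, base_seed: int = 1,
                       rates=TREND_SHEAR_RATES) -> pd.DataFrame:
    """Growth under simple shear across increasing shear rates."""
    rows = []
    for gd in rates:
        params, domain, scen = preset("shear_growth_scaled", gamma_dot=gd)
        for rep in range(replicates):
            s = run(params, domain, scen, seed=_seed(base_seed, rep))
            m = ribbon_morphology(s)
            rows.append({"gamma_dot": gd, "replicate": rep,
                         "roughness": m.roughness, "porosity": m.porosity})
    return pd.DataFrame(rows)


def detachment_trend(replicates: int = 5, base_seed: int = 1,
                     rates=DETACH_SHEAR_RATES) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Erosion of pre-grown films at several shear rates (paired design).

    One film is grown per replicate and each shear rate is applied to a
    copy (the paired protocol of the full-scale study).  Returns
    (per-run summary, per-event table).
    """
    params, domain, grow = preset("detachment_scaled")
    sum_rows, ev_rows = [], []
    for rep in range(replicates):
        g = run(params, domain, grow_only(grow), seed=_seed(base_seed, rep))
        film = g.final
        v0 = float(film.volume(params.internal()).sum())
        for gd in rates:
            shear = dataclasses.replace(grow, max_bio_steps=0,
                                        shear_gamma_dot=gd)
            s = run(params, domain, shear, seed=_seed(base_seed, 500 + rep),
                    initial=film)
            ev = s.detach_events
            n_ev = len(ev)
            total = float(ev.volume.sum()) if n_ev else 0.0
            sum_rows.append({
                "gamma_dot": gd, "replicate": rep, "n_events": n_ev,
                "mean_volume": float(ev.volume.mean()) if n_ev else np.nan,
                "detached_fraction": total / v0,
                "rate": total / shear.shear_duration,
                "film_volume": v0, "n_left": s.final.n})
            if n_ev:
                e = ev.copy()
                e["gamma_dot"] = gd
                e["replicate"] = rep
                e["frac_initial"] = e.volume / v0   # vs pre-shear film
                ev_rows.append(e)
    events = (pd.concat(ev_rows, ignore_index=True)
              if ev_rows else pd.DataFrame())
    return pd.DataFrame(sum_rows), events


def grow_only(scen: Scenario) -> Scenario:
    """Strip the shear phase from a combined scenario."""
    return dataclasses.replace(scen, shear_gamma_dot=None, shear_duration=0.0)
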