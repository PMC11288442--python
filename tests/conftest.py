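import numpy as np
import pandas as pd
import pytest

from equiasym import (
    GaitConfig, PopulationConfig, TrialSummary,
    generate_displacement_trace, generate_population,
)


def brute_force_extrema(z):
    """Independent local-extrema oracle: plain scan, 3-point rule,
    plateaus credited to the earliest sample."""
    maxima, minima = [], []
    for i in range(1, len(z) - 1):
        if z[i] > z[i - 1] and z[i] >= z[i + 1]:
            maxima.append(i)
        if z[i] < z[i - 1] and z[i] <= z[i + 1]:
            minima.append(i)
    return maxima, minima


def brute_force_stride_diffs(trace, intervals):
    """Oracle for the four asymmetry parameters: exhaustive extrema scan
    per stride on the raw samples, second-minus-first extremum value."""
    out = []
    for iv in intervals:
        sel = (trace.time >= iv.start - 1e-9) & (trace.time < iv.end - 1e-9)
        z = trace.z[sel]
        maxima, minima = brute_force_extrema(z)
        if len(maxima) == 2 and len(minima) == 2:
            out.append((z[minima[1]] - z[minima[0]], z[maxima[1]] - z[maxima[0]]))
        else:
            out.append(None)
    return out


def make_summary(horse_id="H0", condition="straight_hard", n_strides=30,
                 duration=0.7, **params) -> TrialSummary:
    """TrialSummary with all means/SDs defaulting to zero."""
    kw = {f"mean_{p}": 0.0 for p in ("hd_min", "hd_max", "pd_min", "pd_max")}
    kw.update({f"sd_{p}": 0.0 for p in ("hd_min", "hd_max", "pd_min", "pd_max")})
    kw.update(params)
    return TrialSummary(horse_id=horse_id, condition=condition,
                        n_strides=n_strides, mean_stride_duration=duration, **kw)


@pytest.fixture(scope="session")
def small_population():
    return generate_population(PopulationConfig(n_horses=200, seed=42))


@pytest.fixture()
def asymmetric_trial():
    return generate_displacement_trace(
        GaitConfig(n_strides=12, asym_hd_min=6.0, asym_hd_max=-3.0,
                   asym_pd_min=2.5, asym_pd_max=-1.5, seed=7)
    )
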