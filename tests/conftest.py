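import numpy as np
import pytest

from meapipe.spikeio import (
    PlateLayout,
    Recording,
    spike_table_from_arrays,
)


def make_recording(
    trains: dict[str, dict[str, list[float]]],
    duration_s: float = 300.0,
    sampling_rate_hz: float = 12500.0,
    layout: PlateLayout | None = None,
) -> Recording:
    """Build a Recording from {well: {electrode: [times]}} literals."""
    layout = layout or PlateLayout()
    times, wells, elecs = [], [], []
    for w, by_elec in trains.items():
        for e, t in by_elec.items():
            times.extend(t)
            wells.extend([w] * len(t))
            elecs.extend([e] * len(t))
    table = spike_table_from_arrays(times, wells, elecs, layout=layout)
    return Recording(table, duration_s=duration_s, sampling_rate_hz=sampling_rate_hz,
                     unit_boundaries_s=(0.0,))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with the package)


def sttc_interval_oracle(a, b, duration, dt):
    """Exact STTC by O(n^2) proximity counting and endpoint-sweep interval union."""
    a = list(map(float, a))
    b = list(map(float, b))
    if not a or not b:
        return float("nan")

    def prop_tiled(x, y):
        hits = 0
        for xi in x:
            if any(abs(xi - yj) <= dt for yj in y):
                hits += 1
        return hits / len(x)

    def covered(x):
        ivals = sorted((max(0.0, xi - dt), min(duration, xi + dt)) for xi in x)
        total = 0.0
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
        if duration - total <= duration * 1e-12:  # same full-coverage snap
            return 1.0
        return total / duration

    pa, pb = prop_tiled(a, b), prop_tiled(b, a)
    ta, tb = covered(a), covered(b)

    def term(p, t):
        if 1.0 - p * t == 0.0:
            return 0.0
        return (p - t) / (1.0 - p * t)

    return 0.5 * (term(pa, tb) + term(pb, ta))


def sttc_raster_oracle(a, b, duration, dt, fs=12500.0):
    """Rasterized STTC for grid-aligned spike times (exact on the grid).

    The coverage term T counts samples in the right-open window
    [i-w, i+w) so that an unclipped window measures exactly 2*dt; the
    proximity term P uses the inclusive window |j - i| <= w.
    """
    n = int(round(duration * fs))
    w = int(round(dt * fs))

    def prox_mask(x):
        m = np.zeros(n + 1, bool)
        for xi in x:
            i = int(round(xi * fs))
            m[max(0, i - w): min(n, i + w) + 1] = True
        return m

    def cover_mask(x):
        m = np.zeros(n, bool)
        for xi in x:
            i = int(round(xi * fs))
            m[max(0, i - w): min(n, i + w)] = True
        return m

    pa = np.mean([prox_mask(b)[int(round(xi * fs))] for xi in a])
    pb = np.mean([prox_mask(a)[int(round(xi * fs))] for xi in b])
    ta = cover_mask(a).mean()
    tb = cover_mask(b).mean()

    def term(p, t):
        return 0.0 if 1.0 - p * t == 0.0 else (p - t) / (1.0 - p * t)

    return 0.5 * (term(pa, tb) + term(pb, ta))


def burst_enumerator(times, max_isi, min_spikes):
    """All maximal contiguous runs with every ISI <= max_isi and >= min_spikes
    (same inclusive 1e-9-relative threshold slack as the detector)."""
    t = list(map(float, times))
    thr = max_isi * (1.0 + 1e-9)
    out = []
    i = 0
    while i < len(t):
        j = i
        while j + 1 < len(t) and t[j + 1] - t[j] <= thr:
            j += 1
        if j - i + 1 >= min_spikes:
            out.append((i, j))
        i = j + 1
    return out


def nb_enumerator(times, elecs, max_isi, min_spikes, min_channels):
    order = sorted(range(len(times)), key=lambda k: (times[k], elecs[k]))
    t = [times[k] for k in order]
    e = [elecs[k] for k in order]
    runs = burst_enumerator(t, max_isi, 1)
    out = []
    for i, j in runs:
        if j - i + 1 >= min_spikes and len(set(e[i: j + 1])) >= min_channels:
            out.append((t[i], t[j], j - i + 1, len(set(e[i: j + 1]))))
    return out
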