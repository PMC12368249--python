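"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, kept structurally different from the
package's algorithms so the two routes can disagree.
"""

from __future__ import annotations

import numpy as np


def brute_bursts(times, max_isi, min_spikes):
    """Exhaustive run-scanner: longest runs with every ISI <= max_isi."""
    times = sorted(times)
    out, run = [], []
    for t in times:
        if not run or t - run[-1] <= max_isi:
            run.append(t)
        else:
            if len(run) >= min_spikes:
                out.append((run[0], run[-1], len(run)))
            run = [t]
    if len(run) >= min_spikes:
        out.append((run[0], run[-1], len(run)))
    return out


def brute_network_bursts(trains, max_isi, min_spikes, min_frac):
    """Pooled-run scanner over (electrode, time) pairs."""
    pooled = sorted(
        (t, e) for e, ts in trains.items() for t in ts
    )
    n_elec = len(trains)
    out, run = [], []
    for item in pooled:
        if not run or item[0] - run[-1][0] <= max_isi:
            run.append(item)
        else:
            if len(run) >= min_spikes and len({e for _, e in run}) / n_elec >= min_frac:
                out.append((run[0][0], run[-1][0], len(run), {e for _, e in run}))
            run = [item]
    if run and len(run) >= min_spikes and len({e for _, e in run}) / n_elec >= min_frac:
        out.append((run[0][0], run[-1][0], len(run), {e for _, e in run}))
    return out


def brute_sttc(a, b, dt, T):
    """Literal transcription of the tiling-coefficient formula.

    P via O(n^2) any-within scans; tiled time via explicit interval union.
    """
    a, b = sorted(a), sorted(b)
    if not a or not b:
        return np.nan

    def prop(x, y):
        return sum(any(abs(xi - yi) <= dt for yi in y) for xi in x) / len(x)

    def tiled(x):
        ivals = sorted((max(xi - dt, 0.0), min(xi + dt, T)) for xi in x)
        total, cs, ce = 0.0, *ivals[0]
        for s, e in ivals[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                total += ce - cs
                cs, ce = s, e
        return (total + ce - cs) / T

    pa, pb = prop(a, b), prop(b, a)
    ta, tb = tiled(a), tiled(b)
    if 1 - pa * tb == 0 or 1 - pb * ta == 0:
        return np.nan
    return 0.5 * ((pa - tb) / (1 - pa * tb) + (pb - ta) / (1 - pb * ta))


def brute_lz76(s: str) -> int:
    """Exhaustive-history parsing by substring search."""
    c, i, n = 0, 0, len(s)
    while i < n:
        k = 1
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        c += 1
        i += min(k, n - i)
    return c
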