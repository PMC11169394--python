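"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's detection code paths: plain
Python loops over samples and exhaustive enumeration over spike
sub-runs and permutations. They encode the published criteria directly
and are only run on small inputs.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def ref_spikes(trace, fs, baseline_amplitude, config):
    """Exhaustive threshold-crossing scan for spikes and artifacts.

    Returns ``(spikes, artifacts)`` as lists of
    ``(peak_time_s, amplitude_uv, width_ms)`` tuples. No high-pass is
    applied; callers should use configs with ``highpass_cutoff=None``.
    """
    x = np.asarray(trace, dtype=float)
    dev = x - float(np.median(x))
    a = np.abs(dev)
    lower = max(
        config.lower_threshold_factor * baseline_amplitude, config.min_peak_height
    )

    # sample-by-sample run scan
    runs = []
    in_run = False
    for i, v in enumerate(a):
        if v >= lower and not in_run:
            in_run, start = True, i
        elif v < lower and in_run:
            runs.append((start, i - 1))
            in_run = False
    if in_run:
        runs.append((start, len(a) - 1))

    candidates = []
    for i0, i1 in runs:
        peak, best = i0, a[i0]
        for i in range(i0, i1 + 1):
            if a[i] > best:
                peak, best = i, a[i]
        candidates.append((peak, float(best), (i1 - i0 + 1) / fs * 1000.0))

    refractory = config.max_peak_width / 1000.0 * fs
    kept = []
    for peak, amp, width in sorted(candidates, key=lambda c: (-c[1], c[0])):
        if all(abs(peak - k[0]) >= refractory for k in kept):
            kept.append((peak, amp, width))

    spikes, artifacts = [], []
    for peak, amp, width in sorted(kept):
        item = (peak / fs, amp, width)
        if amp > config.upper_threshold:
            artifacts.append(item)
        elif width <= config.max_peak_width:
            spikes.append(item)
    return spikes, artifacts


def ref_seizures(spike_times, spike_amps, baseline_amplitude, config):
    """Exhaustive enumeration of maximal qualifying discharge runs.

    Every contiguous sub-run of amplitude-qualifying spikes is checked
    against the ISI band and minimum-duration rule; only maximal runs
    (not extendable on either side) are reported, as ``(start, end)``.
    """
    floor = config.event_amplitude_factor * baseline_amplitude
    qual = [t for t, amp in zip(spike_times, spike_amps) if amp >= floor]
    n = len(qual)

    def in_band(gap):
        return config.seizure_min_isi <= gap < config.seizure_max_isi

    out = []
    for i in range(n):
        for j in range(i, n):
            gaps = [qual[k + 1] - qual[k] for k in range(i, j)]
            if not all(in_band(g) for g in gaps):
                continue
            if i > 0 and in_band(qual[i] - qual[i - 1]):
                continue  # extendable left
            if j < n - 1 and in_band(qual[j + 1] - qual[j]):
                continue  # extendable right
            if qual[j] - qual[i] >= config.seizure_min_duration:
                out.append((qual[i], qual[j]))
    return sorted(set(out))


def ref_events(spike_times, spike_amps, seizures, baseline_amplitude, config):
    """Exhaustive interictal-event clustering, as ``(start, end, n)``."""
    floor = config.event_amplitude_factor * baseline_amplitude
    qual = [
        t
        for t, amp in zip(spike_times, spike_amps)
        if amp >= floor and not any(s <= t <= e for s, e in seizures)
    ]
    clusters, current = [], []
    for t in qual:
        if current and t - current[-1] > config.event_max_isi:
            clusters.append(current)
            current = []
        current.append(t)
    if current:
        clusters.append(current)
    return [
        (c[0], c[-1], len(c)) for c in clusters if len(c) >= config.event_min_spikes
    ]


def ref_mann_whitney(x, y):
    """Exact two-sided Mann–Whitney by complete enumeration.

    Enumerates all C(n1+n2, n1) assignments of the pooled observations
    to obtain the exact permutation distribution of U (handling ties via
    half-counts), then applies the standard exact two-sided rule: twice
    the smaller tail probability, clipped to 1. Returns ``(U_of_x, p)``.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1, n2 = len(x), len(y)

    def u_stat(idx_set):
        xs = [pooled[i] for i in idx_set]
        ys = [pooled[i] for i in range(n1 + n2) if i not in idx_set]
        u = 0.0
        for xi in xs:
            for yi in ys:
                if xi > yi:
                    u += 1.0
                elif xi == yi:
                    u += 0.5
        return u

    u_obs = u_stat(set(range(n1)))
    total = comb(n1 + n2, n1)
    n_le = n_ge = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = u_stat(set(idx))
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    return u_obs, min(1.0, 2.0 * min(n_le, n_ge) / total)


def ref_kaplan_meier(times, events):
    """Hand product-limit estimate: ``(event_times, survival_after)``."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    surv = 1.0
    out_t, out_s = [], []
    for t in sorted(set(times[events == 1])):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        surv *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(surv)
    return out_t, out_s
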