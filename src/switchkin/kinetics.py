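"""Dwell times and transition time constants from decoded traces.

Dwell of a decoded segment = segment length (frames) × frame interval;
segments touching a trace end or a filtered-frame boundary are censored
and excluded by default. The transition time constant τ_ij is the total
decoded time in state i per observed i→j switch (the inverse switching
rate); an analytic counterpart computed directly from a transition matrix
(τ_ij = Δt / A_ij) is provided for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CENSOR_EXCLUDE = "exclude_censored"
CENSOR_INCLUDE = "include_all"


@dataclass
class DwellStats:
    state: int
    mean_min: float
    se_min: float
    n_occurrences: int
    total_frames: int


def dwell_times(
    decoded_traces,
    frame_interval: float | None = None,
    censoring_policy: str = CENSOR_EXCLUDE,
) -> dict:
    """Per-state dwell statistics from decoded traces.

    Returns {state: DwellStats}; states never observed in an uncensored
    segment are absent (never reported as zero).
    """
    if censoring_policy not in (CENSOR_EXCLUDE, CENSOR_INCLUDE):
        raise ValueError(f"unknown censoring_policy {censoring_policy!r}")
    if not isinstance(decoded_traces, (list, tuple)):
        decoded_traces = [decoded_traces]
    dt = frame_interval or decoded_traces[0].frame_interval
    durations: dict[int, list] = {}
    totals: dict[int, int] = {}
    for dec in decoded_traces:
        for seg in dec.segments:
            totals[seg.state] = totals.get(seg.state, 0) + seg.length
            if censoring_policy == CENSOR_EXCLUDE and (
                seg.left_censored or seg.right_censored
            ):
                continue
            durations.setdefault(seg.state, []).append(seg.length * dt)
    out = {}
    for state, vals in sorted(durations.items()):
        arr = np.asarray(vals, dtype=float)
        out[state] = DwellStats(
            state=state,
            mean_min=float(arr.mean()),
            se_min=float(arr.std(ddof=1) / np.sqrt(len(arr)))
            if len(arr) > 1
            else 0.0,
            n_occurrences=len(arr),
            total_frames=totals.get(state, 0),
        )
    return out


def transition_time_constants(
    decoded_traces, frame_interval: float | None = None
):
    """τ_ij matrix from decoded traces.

    τ_ij = (total decoded time in state i) / (# observed i→j switches);
    entries with zero observed switches are NaN. Returns (tau, n_switches)
    as (K, K) arrays with K = max decoded state + 1. Switches are only
    counted between consecutive frames of one chain segment.
    """
    if not isinstance(decoded_traces, (list, tuple)):
        decoded_traces = [decoded_traces]
    dt = frame_interval or decoded_traces[0].frame_interval
    K = 0
    for dec in decoded_traces:
        valid = dec.states[dec.states >= 0]
        if len(valid):
            K = max(K, int(valid.max()) + 1)
    if K == 0:
        raise ValueError("no decoded frames")
    time_in = np.zeros(K)
    n_switch = np.zeros((K, K), dtype=np.int64)
    for dec in decoded_traces:
        order = sorted(dec.segments, key=lambda s: s.start)
        for seg in order:
            time_in[seg.state] += seg.length * dt
        # consecutive segments within one chain: a right-uncensored segment
        # is followed immediately by the next segment in the same chain
        for a, b in zip(order, order[1:]):
            if not a.right_censored and a.start + a.length == b.start:
                n_switch[a.state, b.state] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(n_switch > 0, time_in[:, None] / n_switch, np.nan)
    np.fill_diagonal(tau, np.nan)
    return tau, n_switch


def tau_from_transition_matrix(model) -> np.ndarray:
    """Analytic transition time constants implied by a fitted transition
    matrix: τ_ij = Δt / A_ij (expected time in i per i→j event)."""
    A = np.asarray(model.transmat, dtype=float)
    with np.errstate(divide="ignore"):
        tau = np.where(A > 0, model.frame_interval / A, np.nan)
    np.fill_diagonal(tau, np.nan)
    return tau


@dataclass
class KineticsSummary:
    """Per-state production/dwell table plus the τ_ij matrix (a
    reproduction of the headline kinetics table for a fitted dataset)."""

    table: pd.DataFrame
    tau: np.ndarray
    tau_counts: np.ndarray
    tau_model: np.ndarray
    state_labels: list


def summarize_kinetics(
    model, traces, decoded_traces, censoring_policy: str = CENSOR_EXCLUDE
) -> KineticsSummary:
    """Assemble the per-state kinetics summary for decoded traces:
    mean production per channel, frames, dwell time (decoded-segment and
    model-implied), occurrences, and both τ estimators."""
    K = model.n_states
    dt = model.frame_interval
    all_states = np.concatenate([d.states for d in decoded_traces])
    all_counts = np.vstack([t.counts for t in traces])
    if len(all_states) != len(all_counts):
        raise ValueError("decoded traces do not match input traces")
    dstats = dwell_times(decoded_traces, dt, censoring_policy)
    model_dwell = model.dwell_means()
    rows = []
    labels = model.state_labels()
    for k in range(K):
        sel = all_states == k
        nk = int(sel.sum())
        rows.append(
            {
                "state": k,
                "label": labels[k],
                "mean_cro": float(all_counts[sel, 0].mean()) if nk else np.nan,
                "mean_ci": float(all_counts[sel, 1].mean()) if nk else np.nan,
                "n_frames": nk,
                "dwell_min": dstats[k].mean_min if k in dstats else np.nan,
                "dwell_se": dstats[k].se_min if k in dstats else np.nan,
                "dwell_model_min": float(model_dwell[k]),
                "occurrences": dstats[k].n_occurrences if k in dstats else 0,
            }
        )
    tau, counts = transition_time_constants(decoded_traces, dt)
    # pad to K states if some state was never decoded
    if tau.shape[0] < K:
        pad = K - tau.shape[0]
        tau = np.pad(tau, ((0, pad), (0, pad)), constant_values=np.nan)
        counts = np.pad(counts, ((0, pad), (0, pad)))
    return KineticsSummary(
        table=pd.DataFrame(rows),
        tau=tau,
        tau_counts=counts,
        tau_model=tau_from_transition_matrix(model),
        state_labels=labels,
    )
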