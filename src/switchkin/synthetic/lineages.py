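"""Lineage-trace and snapshot generators.

Each lineage is a hidden Markov state path with state-conditioned count
emissions (Poisson per channel by default, negative binomial optional),
overlaid with a cell-cycle clock: cycle lengths are truncated-normal
(floor one frame), division resets cell age but NOT the hidden state
(production state is a promoter configuration that daughters inherit),
and counts are per-cell so no partitioning is applied at division.

Optional effects: a per-molecule exponential maturation lag (rounded to
frame boundaries) shifting detection frames, and binomial thinning for
imperfect detection.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import truncnorm

from switchkin.synthetic.markov import simulate_state_path
from switchkin.traces import LineageTrace


def _sample_counts(rng, lam, config):
    """Counts for an array of per-frame emission means."""
    lam = np.asarray(lam, dtype=float)
    if config is not None and config.emission_family == "negative_binomial":
        r = config.nb_dispersion
        # NB with mean lam, shape r: p = r / (r + lam)
        out = np.zeros(lam.shape, dtype=np.int64)
        pos = lam > 0
        out[pos] = rng.negative_binomial(r, r / (r + lam[pos]))
        return out
    return rng.poisson(lam)


def _sample_cycles(rng, config, total_minutes):
    """Cycle lengths (whole frames, >= 1) covering at least total_minutes."""
    dt = config.frame_interval
    lengths = []
    covered = 0.0
    a = (dt - config.cell_cycle_mean) / max(config.cell_cycle_sd, 1e-12)
    while covered < total_minutes:
        if config.cell_cycle_sd == 0:
            L = config.cell_cycle_mean
        else:
            L = truncnorm.rvs(
                a, np.inf,
                loc=config.cell_cycle_mean,
                scale=config.cell_cycle_sd,
                random_state=rng,
            )
        n_frames = max(1, int(round(L / dt)))
        lengths.append(n_frames)
        covered += n_frames * dt
    return lengths


def _apply_maturation(rng, counts, mean_lag_min, frame_interval):
    """Shift each molecule's detection frame by an exponential lag rounded
    to frames; molecules maturing past the trace end are not observed."""
    n = len(counts)
    out = np.zeros(n, dtype=np.int64)
    src = np.repeat(np.arange(n), counts)
    if len(src) == 0:
        return out
    lags = rng.exponential(mean_lag_min, size=len(src))
    dest = src + np.round(lags / frame_interval).astype(np.int64)
    dest = dest[dest < n]
    np.add.at(out, dest, 1)
    return out


def simulate_lineage(config, model, seed: int = 0, lineage_id: str = "L000") -> LineageTrace:
    """One lineage trace of ``config.trace_length`` frames from ``model``."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.trace_length
    dt = config.frame_interval

    path = simulate_state_path(model, n, seed=rng.integers(2**31))
    lam = model.means[path.states]  # (n, 2)
    cro = _sample_counts(rng, lam[:, 0], config)
    ci = _sample_counts(rng, lam[:, 1], config)

    if config.maturation_mean > 0:
        cro = _apply_maturation(rng, cro, config.maturation_mean, dt)
        ci = _apply_maturation(rng, ci, config.maturation_mean, dt)

    if config.detection_efficiency < 1.0:
        cro = rng.binomial(cro, config.detection_efficiency)
        ci = rng.binomial(ci, config.detection_efficiency)

    cycles = _sample_cycles(rng, config, n * dt)
    cell_age = np.empty(n, dtype=float)
    cell_id = np.empty(n, dtype=np.int64)
    division = np.zeros(n, dtype=bool)
    t = 0
    for gen, n_frames in enumerate(cycles):
        for i in range(n_frames):
            if t >= n:
                break
            cell_age[t] = (i + 1) / n_frames
            cell_id[t] = gen
            division[t] = gen > 0 and i == 0  # first frame of a new cell
            t += 1
        if t >= n:
            break

    return LineageTrace(
        lineage_id=lineage_id,
        frame_interval=dt,
        time_min=np.arange(n) * dt,
        cro=cro,
        ci=ci,
        cell_age=cell_age,
        division_flag=division,
        cell_id=cell_id,
        true_state=path.states,
    )


def simulate_dataset(config, model, seed: int = 0) -> list[LineageTrace]:
    """Independent lineages with per-lineage derived seeds (reproducible)."""
    config.validate()
    seeds = np.random.SeedSequence(seed).spawn(config.n_lineages)
    out = []
    for i, ss in enumerate(seeds):
        child = int(ss.generate_state(1)[0] % (2**31))
        out.append(
            simulate_lineage(config, model, seed=child, lineage_id=f"L{i:03d}")
        )
    return out


def simulate_snapshot_population(config, model, n_cells: int, seed: int = 0):
    """Per-cell cumulative (CI_total, Cro_total) over one sampled cell
    cycle — a steady-state stand-in for integrated fluorescence.

    Returns a pandas DataFrame with columns cell_id, ci_total, cro_total.
    """
    import pandas as pd

    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    config.validate()
    rng = np.random.default_rng(seed)
    pi = model.stationary_distribution()
    start_model_pi = pi

    ci_tot = np.empty(n_cells, dtype=np.int64)
    cro_tot = np.empty(n_cells, dtype=np.int64)
    cum_A = np.cumsum(model.transmat, axis=1)
    cum_pi = np.cumsum(start_model_pi)
    for c in range(n_cells):
        n_frames = _sample_cycles(rng, config, config.frame_interval)[0]
        s = int(np.searchsorted(cum_pi, rng.random(), side="right"))
        s = min(s, model.n_states - 1)
        cro_sum = ci_sum = 0
        for _ in range(n_frames):
            lam = model.means[s]
            cro_sum += int(_sample_counts(rng, np.array([lam[0]]), config)[0])
            ci_sum += int(_sample_counts(rng, np.array([lam[1]]), config)[0])
            s = int(
                np.searchsorted(cum_A[s], rng.random(), side="right")
            )
            s = min(s, model.n_states - 1)
        cro_tot[c] = cro_sum
        ci_tot[c] = ci_sum
    return pd.DataFrame(
        {"cell_id": np.arange(n_cells), "ci_total": ci_tot, "cro_total": cro_tot}
    )
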