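"""Exact stochastic (Gillespie) simulation of promoter-operator occupancy.

State space: three operators (O_R1, O_R2, O_R3), each free (0), CI-bound
(1) or Cro-bound (2); mRNA counts for each gene; free protein pools.
Promoter logic: P_R (cro) fires iff O_R1 AND O_R2 are free of repressor;
P_RM (cI) fires iff O_R3 is free. Transcription spawns mRNAs with
exponential lifetime; each mRNA translates at rate burst_size/lifetime
(mean burst per mRNA = burst_size); proteins dilute/decay with exponential
lifetime. Binding propensity is dimer-like, rate * n(n-1)/2, and binding
sequesters one molecule from the free pool (returned on unbinding).
``adiabaticity_scale`` multiplies binding and unbinding rates only.

Protein-production event times are binned into frames to produce a
LineageTrace; cell-cycle bookkeeping (ages, division flags) is annotated
from the same truncated-normal cycle model as the lineage generator and
does not feed back on the chemistry.
"""

from __future__ import annotations

import math
import random

import numpy as np

from switchkin.traces import LineageTrace

FREE, CI_BOUND, CRO_BOUND = 0, 1, 2


def simulate_promoter_mechanism(
    mconfig,
    duration: float,
    seed: int = 0,
    frame_interval: float = 5.0,
    generator_config=None,
    lineage_id: str = "M000",
) -> LineageTrace:
    """Simulate the operator-occupancy mechanism for ``duration`` minutes
    and bin protein-production events into frames of ``frame_interval``."""
    mconfig.validate()
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rnd = random.Random(seed)
    s = mconfig.adiabaticity_scale
    ci_on = [r * s for r in mconfig.ci_on]
    ci_off = [r * s for r in mconfig.ci_off]
    cro_on = [r * s for r in mconfig.cro_on]
    cro_off = [r * s for r in mconfig.cro_off]
    k_tl = mconfig.burst_size / mconfig.mrna_lifetime
    k_rna_dec = 1.0 / mconfig.mrna_lifetime
    k_prot_dec = 1.0 / mconfig.protein_lifetime

    ops = [FREE, FREE, FREE]
    n_ci = mconfig.init_ci
    n_cro = mconfig.init_cro
    m_ci = 0
    m_cro = 0

    n_frames = int(math.ceil(duration / frame_interval))
    cro_counts = np.zeros(n_frames, dtype=np.int64)
    ci_counts = np.zeros(n_frames, dtype=np.int64)

    t = 0.0
    log = math.log
    while True:
        # propensities
        props = []
        events = []
        for o in range(3):
            if ops[o] == FREE:
                a = ci_on[o] * n_ci * (n_ci - 1) / 2.0
                if a > 0:
                    props.append(a)
                    events.append(("bind_ci", o))
                a = cro_on[o] * n_cro * (n_cro - 1) / 2.0
                if a > 0:
                    props.append(a)
                    events.append(("bind_cro", o))
            elif ops[o] == CI_BOUND:
                if ci_off[o] > 0:
                    props.append(ci_off[o])
                    events.append(("unbind_ci", o))
            else:
                if cro_off[o] > 0:
                    props.append(cro_off[o])
                    events.append(("unbind_cro", o))
        pr_active = ops[0] == FREE and ops[1] == FREE
        prm_active = ops[2] == FREE
        if pr_active and mconfig.k_pr > 0:
            props.append(mconfig.k_pr)
            events.append(("tx_cro", -1))
        if prm_active and mconfig.k_prm > 0:
            props.append(mconfig.k_prm)
            events.append(("tx_ci", -1))
        if m_cro > 0:
            props.append(m_cro * k_rna_dec)
            events.append(("dec_m_cro", -1))
            props.append(m_cro * k_tl)
            events.append(("tl_cro", -1))
        if m_ci > 0:
            props.append(m_ci * k_rna_dec)
            events.append(("dec_m_ci", -1))
            props.append(m_ci * k_tl)
            events.append(("tl_ci", -1))
        if n_cro > 0:
            props.append(n_cro * k_prot_dec)
            events.append(("dec_cro", -1))
        if n_ci > 0:
            props.append(n_ci * k_prot_dec)
            events.append(("dec_ci", -1))

        total = sum(props)
        if total <= 0.0:
            break  # clean termination: nothing can happen any more
        t += -log(1.0 - rnd.random()) / total
        if t >= duration:
            break
        u = rnd.random() * total
        acc = 0.0
        chosen = events[-1]
        for a, ev in zip(props, events):
            acc += a
            if u <= acc:
                chosen = ev
                break
        kind, o = chosen
        if kind == "bind_ci":
            ops[o] = CI_BOUND
            n_ci -= 1
        elif kind == "bind_cro":
            ops[o] = CRO_BOUND
            n_cro -= 1
        elif kind == "unbind_ci":
            ops[o] = FREE
            n_ci += 1
        elif kind == "unbind_cro":
            ops[o] = FREE
            n_cro += 1
        elif kind == "tx_cro":
            m_cro += 1
        elif kind == "tx_ci":
            m_ci += 1
        elif kind == "dec_m_cro":
            m_cro -= 1
        elif kind == "dec_m_ci":
            m_ci -= 1
        elif kind == "tl_cro":
            n_cro += 1
            cro_counts[int(t / frame_interval)] += 1
        elif kind == "tl_ci":
            n_ci += 1
            ci_counts[int(t / frame_interval)] += 1
        elif kind == "dec_cro":
            n_cro -= 1
        elif kind == "dec_ci":
            n_ci -= 1

    # annotate cell-cycle bookkeeping (no feedback on chemistry)
    from switchkin.config import GeneratorConfig
    from switchkin.synthetic.lineages import _sample_cycles

    gc = generator_config or GeneratorConfig(frame_interval=frame_interval)
    rng = np.random.default_rng(seed + 1)
    cycles = _sample_cycles(rng, gc, n_frames * frame_interval)
    cell_age = np.empty(n_frames, dtype=float)
    cell_id = np.empty(n_frames, dtype=np.int64)
    division = np.zeros(n_frames, dtype=bool)
    idx = 0
    for gen, nf in enumerate(cycles):
        for i in range(nf):
            if idx >= n_frames:
                break
            cell_age[idx] = (i + 1) / nf
            cell_id[idx] = gen
            division[idx] = gen > 0 and i == 0
            idx += 1
        if idx >= n_frames:
            break

    return LineageTrace(
        lineage_id=lineage_id,
        frame_interval=frame_interval,
        time_min=np.arange(n_frames) * frame_interval,
        cro=cro_counts,
        ci=ci_counts,
        cell_age=cell_age,
        division_flag=division,
        cell_id=cell_id,
    )
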