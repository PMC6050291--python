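"""K-state HMM with per-state bivariate count emissions.

Fitting is Baum–Welch EM over multiple traces (scaled forward–backward,
batched across chain segments); decoding is Viterbi with deterministic
tie-breaking toward the lower state index; model selection offers BIC and
a histogram-match criterion (distance between the model-predicted and the
observed 2D production histogram). Emissions are independent Poisson per
channel given the state (negative binomial optional); chain segments are
never bridged (young-cell filtering boundaries break the chain, cell
divisions by default do not).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from switchkin.model import HMMModel, ReducibleChainError

_LOG_ZERO = -745.0  # exp() underflows to exactly 0.0


# ---------------------------------------------------------------------------
# Emission log-pmfs
# ---------------------------------------------------------------------------

def _log_emission(counts: np.ndarray, model: HMMModel) -> np.ndarray:
    """log P(frame | state) for (T, 2) counts; returns (T, K)."""
    x = np.asarray(counts, dtype=float)
    lam = model.means  # (K, 2)
    if model.emission == "poisson":
        loglam = np.where(lam > 0, np.log(np.maximum(lam, 1e-300)), _LOG_ZERO)
        # sum over channels: x * log(lam) - lam - ln(x!)
        out = (
            x @ loglam.T
            - lam.sum(axis=1)[None, :]
            - gammaln(x + 1).sum(axis=1)[:, None]
        )
    elif model.emission == "negative_binomial":
        r = model.dispersion
        logp = np.where(
            lam > 0, np.log(np.maximum(lam, 1e-300)) - np.log(r + lam), _LOG_ZERO
        )
        log1mp = -np.log1p(lam / r)  # = log(r / (r + lam))
        out = np.zeros((x.shape[0], lam.shape[0]))
        for c in range(2):
            xc = x[:, c : c + 1]
            out += (
                gammaln(xc + r)
                - gammaln(r)
                - gammaln(xc + 1)
                + r * log1mp[None, :, c]
                + xc * logp[None, :, c].reshape(1, -1)
            )
    else:  # pragma: no cover
        raise ValueError(f"unknown emission family {model.emission!r}")
    # a channel with mean exactly 0 has zero mass on positive counts
    impossible = ((lam[None, :, :] == 0) & (x[:, None, :] > 0)).any(axis=2)
    out[impossible] = -np.inf
    return out


# ---------------------------------------------------------------------------
# Segment extraction
# ---------------------------------------------------------------------------

def trace_segments(trace, break_on_division: bool = False) -> list[np.ndarray]:
    """Index arrays of chain segments for one trace. Filtered-frame
    boundaries (segment_id changes) always break the chain; division
    frames only when requested."""
    segs = []
    for idx in trace.segments():
        if break_on_division:
            div = trace.division_flag[idx]
            cuts = np.flatnonzero(div[1:]) + 1 if len(idx) > 1 else []
            start = 0
            boundaries = list(np.flatnonzero(div)) if len(idx) else []
            pieces = np.split(np.arange(len(idx)), boundaries) if boundaries else [np.arange(len(idx))]
            for piece in pieces:
                if len(piece):
                    segs.append(idx[piece])
        else:
            segs.append(idx)
    return [s for s in segs if len(s)]


def _gather_segments(traces, break_on_division=False):
    out = []
    for tr in traces:
        for idx in trace_segments(tr, break_on_division):
            out.append(tr.counts[idx])
    return out


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------

def _forward_scaled(logB: np.ndarray, model: HMMModel):
    """Scaled forward pass for one segment. Returns (alpha, log_c, logL);
    logL may be -inf when a frame has zero emission mass in every state."""
    T, K = logB.shape
    A = model.transmat
    shift = logB.max(axis=1)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    B = np.exp(logB - shift[:, None])
    alpha = np.empty((T, K))
    log_c = np.empty(T)
    a = model.startprob * B[0]
    c = a.sum()
    if c <= 0:
        return None, None, -np.inf
    alpha[0] = a / c
    log_c[0] = np.log(c) + shift[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c = a.sum()
        if c <= 0:
            return None, None, -np.inf
        alpha[t] = a / c
        log_c[t] = np.log(c) + shift[t]
    return alpha, log_c, float(log_c.sum())


def _backward_scaled(logB, model, log_c):
    T, K = logB.shape
    A = model.transmat
    shift = logB.max(axis=1)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    B = np.exp(logB - shift[:, None])
    c = np.exp(log_c - shift)  # local scale factors
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    return beta


def loglikelihood(model: HMMModel, trace, break_on_division: bool = False) -> float:
    """log P(observations | model) over all chain segments of a trace.

    Returns -inf (with no exception) when some frame has zero emission
    probability in every state.
    """
    model.validate()
    total = 0.0
    for idx in trace_segments(trace, break_on_division):
        logB = _log_emission(trace.counts[idx], model)
        _, _, ll = _forward_scaled(logB, model)
        if not np.isfinite(ll):
            return -np.inf
        total += ll
    return total


def posteriors(model: HMMModel, counts: np.ndarray) -> np.ndarray:
    """Forward–backward posterior state probabilities for one segment."""
    logB = _log_emission(counts, model)
    alpha, log_c, ll = _forward_scaled(logB, model)
    if alpha is None:
        raise FloatingPointError("zero emission probability row")
    beta = _backward_scaled(logB, model, log_c)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma


# ---------------------------------------------------------------------------
# Batched EM
# ---------------------------------------------------------------------------

def _batch(segments):
    S = len(segments)
    T = max(len(s) for s in segments)
    X = np.zeros((S, T, 2))
    mask = np.zeros((S, T), dtype=bool)
    for i, seg in enumerate(segments):
        X[i, : len(seg)] = seg
        mask[i, : len(seg)] = True
    return X, mask


def _em_pass(X, mask, lengths, means, A, pi, emission, dispersion):
    """One batched E-step + sufficient statistics. Returns
    (logL, gamma_sum(K), gamma_x(K,2), xi_sum(K,K), gamma0(K), gamma_full)."""
    S, T, _ = X.shape
    K = means.shape[0]
    tmp_model = HMMModel(
        means=means, transmat=A, startprob=pi, emission=emission,
        dispersion=dispersion,
    )
    flatX = X.reshape(S * T, 2)
    logB = _log_emission(flatX, tmp_model).reshape(S, T, K)
    shift = logB.max(axis=2)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    B = np.exp(logB - shift[..., None])

    alpha = np.zeros((S, T, K))
    cs = np.ones((S, T))
    a = pi[None, :] * B[:, 0, :]
    c = a.sum(axis=1)
    bad = c <= 0
    c = np.where(bad, 1.0, c)
    alpha[:, 0, :] = a / c[:, None]
    cs[:, 0] = c
    for t in range(1, T):
        act = mask[:, t]
        a = (alpha[:, t - 1, :] @ A) * B[:, t, :]
        c = a.sum(axis=1)
        c = np.where(c <= 0, 1.0, c)
        anew = a / c[:, None]
        alpha[:, t, :] = np.where(act[:, None], anew, alpha[:, t - 1, :])
        cs[:, t] = np.where(act, c, 1.0)
    logL = float((np.log(cs[mask])).sum() + shift[mask].sum())

    beta = np.zeros((S, T, K))
    # beta = 1 at each sequence's last frame
    last = lengths - 1
    beta[np.arange(S), last, :] = 1.0
    for t in range(T - 2, -1, -1):
        act = mask[:, t + 1]
        b = (B[:, t + 1, :] * beta[:, t + 1, :]) @ A.T
        b = b / cs[:, t + 1][:, None]
        # inactive t+1 (sequence already ended): keep the initialized value
        # (1.0 at each sequence's true last frame, 0 in the padding)
        beta[:, t, :] = np.where(act[:, None], b, beta[:, t, :])

    gamma = alpha * beta
    norm = gamma.sum(axis=2, keepdims=True)
    norm = np.where(norm <= 0, 1.0, norm)
    gamma = gamma / norm
    gamma = gamma * mask[..., None]

    gamma_sum = gamma.sum(axis=(0, 1))
    gamma_x = np.einsum("stk,stc->kc", gamma, X * mask[..., None])
    gamma0 = gamma[:, 0, :].sum(axis=0)

    # xi: transitions t -> t+1 where frame t+1 is active
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        act = mask[:, t + 1]
        if not act.any():
            continue
        w = (B[:, t + 1, :] * beta[:, t + 1, :]) / cs[:, t + 1][:, None]
        xi_t = np.einsum(
            "si,ij,sj->ij", alpha[:, t, :] * act[:, None], A, w
        )
        xi_sum += xi_t
    return logL, gamma_sum, gamma_x, xi_sum, gamma0, gamma


def _kmeans(points, K, rng, n_iter=50):
    """Small deterministic k-means++ on (n, 2) count pairs."""
    n = len(points)
    pts = np.asarray(points, dtype=float)
    centers = np.empty((K, 2))
    centers[0] = pts[rng.integers(n)]
    for k in range(1, K):
        d2 = np.min(
            ((pts[:, None, :] - centers[None, :k, :]) ** 2).sum(axis=2), axis=1
        )
        tot = d2.sum()
        if tot <= 0:
            centers[k] = pts[rng.integers(n)] + rng.normal(0, 0.5, 2)
            continue
        centers[k] = pts[np.searchsorted(np.cumsum(d2 / tot), rng.random())]
    for _ in range(n_iter):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        lab = d2.argmin(axis=1)
        new = centers.copy()
        for k in range(K):
            sel = lab == k
            if sel.any():
                new[k] = pts[sel].mean(axis=0)
        if np.allclose(new, centers):
            break
        centers = new
    return centers


@dataclass
class FitResult:
    model: HMMModel
    log_likelihood: float
    n_iter: int
    converged: bool
    restart_log_likelihoods: list
    restart_degenerate: list
    ll_history: list = field(default_factory=list)


def fit_em(
    traces,
    K: int,
    init_strategy: str = "kmeans",
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    emission: str = "poisson",
    dispersion: float = 10.0,
    break_on_division: bool = False,
    frame_interval: float | None = None,
) -> FitResult:
    """Baum–Welch EM over multiple traces; best of ``n_restarts`` returned.

    Restarts in which some state's expected occupancy drops below one frame
    are flagged degenerate and excluded from the best-of selection (unless
    every restart is degenerate).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not traces:
        raise ValueError("need at least one trace")
    dt = frame_interval or traces[0].frame_interval
    segments = _gather_segments(traces, break_on_division)
    X, mask = _batch(segments)
    lengths = mask.sum(axis=1)
    pooled = np.vstack(segments).astype(float)
    n_frames = len(pooled)

    root = np.random.SeedSequence(seed)
    restart_seeds = root.spawn(n_restarts)

    best = None
    restart_lls, restart_deg = [], []
    for ridx, ss in enumerate(restart_seeds):
        rng = np.random.default_rng(ss)
        if init_strategy == "kmeans":
            means = _kmeans(pooled, K, rng)
        elif init_strategy == "random":
            means = pooled[rng.integers(n_frames, size=K)].astype(float)
        else:
            raise ValueError(f"unknown init_strategy {init_strategy!r}")
        means = np.maximum(means + rng.uniform(0, 0.1, size=(K, 2)), 1e-3)
        A = np.full((K, K), 0.1 / max(K - 1, 1))
        np.fill_diagonal(A, 0.9 if K > 1 else 1.0)
        pi = np.full(K, 1.0 / K)

        prev_ll = -np.inf
        history = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            logL, gsum, gx, xi, g0, _ = _em_pass(
                X, mask, lengths, means, A, pi, emission, dispersion
            )
            history.append(logL)
            if np.isfinite(prev_ll) and logL < prev_ll - 1e-8:
                break  # numerical trouble; keep previous parameters
            # M-step
            denom = np.maximum(gsum, 1e-12)
            means = np.maximum(gx / denom[:, None], 1e-4)
            if K > 1:
                rows = xi.sum(axis=1, keepdims=True)
                A = np.where(rows > 1e-12, xi / np.maximum(rows, 1e-12), A)
                A = A / A.sum(axis=1, keepdims=True)
            pi = np.maximum(g0, 1e-12)
            pi = pi / pi.sum()
            if np.isfinite(prev_ll) and abs(logL - prev_ll) < tol * abs(prev_ll):
                converged = True
                break
            prev_ll = logL

        final_ll, gsum, *_ = _em_pass(
            X, mask, lengths, means, A, pi, emission, dispersion
        )
        degenerate = bool(np.any(gsum < 1.0))
        restart_lls.append(final_ll)
        restart_deg.append(degenerate)
        cand = dict(
            means=means, A=A, pi=pi, ll=final_ll, it=it,
            converged=converged, history=history, degenerate=degenerate,
        )
        if best is None:
            best = cand
        else:
            better = final_ll > best["ll"]
            if best["degenerate"] and not degenerate:
                best = cand
            elif (degenerate == best["degenerate"]) and better:
                best = cand

    model = HMMModel(
        means=best["means"],
        transmat=best["A"],
        startprob=best["pi"],
        frame_interval=dt,
        emission=emission,
        dispersion=dispersion,
    )
    return FitResult(
        model=model,
        log_likelihood=best["ll"],
        n_iter=best["it"],
        converged=best["converged"],
        restart_log_likelihoods=restart_lls,
        restart_degenerate=restart_deg,
        ll_history=best["history"],
    )


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    selected_K: int
    criterion: str
    table: "object"  # pandas DataFrame: K, logL, n_params, bic, tv_distance
    fits: dict


def n_parameters(K: int) -> int:
    """Free parameters: K*2 emission means + K(K-1) transitions + K-1 start."""
    return 2 * K + K * (K - 1) + (K - 1)


def select_model(
    traces,
    K_range,
    criterion: str = "bic",
    tie_tol: float = 0.005,
    **fit_kwargs,
) -> SelectionResult:
    """Fit each K and select by BIC (default) or histogram match (total
    variation between predicted and observed 2D histograms; smallest K
    within ``tie_tol`` of the minimum wins)."""
    import pandas as pd

    from switchkin.landscape import histogram2d

    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    if criterion not in ("bic", "histmatch"):
        raise ValueError("criterion must be 'bic' or 'histmatch'")
    obs = histogram2d(traces)
    n_frames = obs.n_frames
    rows = []
    fits = {}
    for K in K_range:
        fit = fit_em(traces, K, **fit_kwargs)
        fits[K] = fit
        bic = -2.0 * fit.log_likelihood + n_parameters(K) * np.log(n_frames)
        pred = predicted_histogram(fit.model, max_count=obs.max_count)
        tv = 0.5 * float(
            np.abs(pred.probabilities - obs.probabilities).sum()
        )
        rows.append(
            {"K": K, "logL": fit.log_likelihood, "n_params": n_parameters(K),
             "bic": bic, "tv_distance": tv}
        )
    table = pd.DataFrame(rows)
    bic_K = int(table.loc[table["bic"].idxmin(), "K"])
    tv_min = table["tv_distance"].min()
    hist_K = int(table.loc[table["tv_distance"] <= tv_min + tie_tol, "K"].min())
    selected = bic_K if criterion == "bic" else hist_K
    table["selected_bic"] = table["K"] == bic_K
    table["selected_histmatch"] = table["K"] == hist_K
    return SelectionResult(
        selected_K=selected, criterion=criterion, table=table, fits=fits
    )


def predicted_histogram(model: HMMModel, max_count: int = 20):
    """Stationary-mixture 2D count histogram predicted by the model:
    P(cro, ci) = sum_k pi_k * pmf_k(cro) * pmf_k(ci), with tail mass above
    ``max_count`` pooled into the top bin. Closed form, no sampling."""
    from scipy import stats

    from switchkin.landscape import ProductionHistogram2D

    pi = model.stationary_distribution()  # raises ReducibleChainError if not unique
    grid = np.arange(max_count + 1)
    P = np.zeros((max_count + 1, max_count + 1))
    for k in range(model.n_states):
        pmfs = []
        for c in range(2):
            lam = model.means[k, c]
            if model.emission == "poisson":
                pmf = stats.poisson.pmf(grid, lam)
                tail = stats.poisson.sf(max_count, lam)
            else:
                r = model.dispersion
                p = r / (r + lam) if lam > 0 else 1.0
                pmf = stats.nbinom.pmf(grid, r, p)
                tail = stats.nbinom.sf(max_count, r, p)
            pmf = pmf.copy()
            pmf[-1] += tail
            pmfs.append(pmf)
        P += pi[k] * np.outer(pmfs[0], pmfs[1])
    return ProductionHistogram2D(
        probabilities=P / P.sum(), n_frames=0, max_count=max_count
    )


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    state: int
    start: int
    length: int
    left_censored: bool
    right_censored: bool


@dataclass
class DecodedTrace:
    states: np.ndarray
    posterior: np.ndarray
    segments: list
    frame_interval: float
    lineage_id: str = ""


def viterbi(model: HMMModel, trace, break_on_division: bool = False) -> DecodedTrace:
    """Maximum-a-posteriori state path (per chain segment) with posterior
    probabilities; ties broken deterministically toward the lower index."""
    model.validate()
    n = len(trace)
    K = model.n_states
    states = np.full(n, -1, dtype=np.int64)
    post = np.full((n, K), np.nan)
    seg_list = []
    logA = np.where(
        model.transmat > 0, np.log(np.maximum(model.transmat, 1e-300)), _LOG_ZERO
    )
    logpi = np.where(
        model.startprob > 0, np.log(np.maximum(model.startprob, 1e-300)), _LOG_ZERO
    )
    for idx in trace_segments(trace, break_on_division):
        counts = trace.counts[idx]
        logB = _log_emission(counts, model)
        T = len(idx)
        delta = np.empty((T, K))
        psi = np.zeros((T, K), dtype=np.int64)
        delta[0] = logpi + logB[0]
        for t in range(1, T):
            cand = delta[t - 1][:, None] + logA
            psi[t] = cand.argmax(axis=0)  # argmax takes the first (lowest) index
            delta[t] = cand[psi[t], np.arange(K)] + logB[t]
        path = np.empty(T, dtype=np.int64)
        path[T - 1] = int(delta[T - 1].argmax())
        for t in range(T - 2, -1, -1):
            path[t] = psi[t + 1][path[t + 1]]
        states[idx] = path
        post[idx] = posteriors(model, counts)
        # runs within this chain segment
        run_start = 0
        for t in range(1, T + 1):
            if t == T or path[t] != path[run_start]:
                seg_list.append(
                    Segment(
                        state=int(path[run_start]),
                        start=int(idx[run_start]),
                        length=t - run_start,
                        left_censored=run_start == 0,
                        right_censored=t == T,
                    )
                )
                run_start = t
    return DecodedTrace(
        states=states,
        posterior=post,
        segments=seg_list,
        frame_interval=model.frame_interval,
        lineage_id=getattr(trace, "lineage_id", ""),
    )
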