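"""Hidden-Markov model container shared by the generator and the fitter."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ModelError(ValueError):
    """Raised when an HMMModel violates its invariants."""


class ReducibleChainError(ModelError):
    """Transition matrix has no unique stationary distribution."""

    def __init__(self, blocks):
        self.blocks = blocks
        super().__init__(
            "transition matrix is reducible; closed communicating blocks: "
            + ", ".join(str(sorted(b)) for b in blocks)
        )


@dataclass
class HMMModel:
    """K-state HMM with independent per-channel count emissions.

    ``means`` is a (K, 2) array of per-state (lambda_cro, lambda_ci)
    emission means in molecules/frame. ``transmat`` is the per-frame
    row-stochastic transition matrix; ``startprob`` the initial state
    distribution. ``emission`` selects the count family ('poisson' or
    'negative_binomial' with shared ``dispersion`` r).
    """

    means: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    frame_interval: float = 5.0
    emission: str = "poisson"
    dispersion: float = 10.0

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.transmat = np.atleast_2d(np.asarray(self.transmat, dtype=float))
        self.startprob = np.atleast_1d(np.asarray(self.startprob, dtype=float))
        self.validate()

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    def validate(self) -> None:
        K = self.n_states
        if self.means.shape != (K, 2):
            raise ModelError("means must have shape (K, 2)")
        if np.any(self.means < 0):
            raise ModelError("emission means must be >= 0")
        if self.transmat.shape != (K, K):
            raise ModelError("transmat must be (K, K)")
        if np.any(self.transmat < -1e-12):
            raise ModelError("transmat entries must be >= 0")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-8):
            raise ModelError("transmat rows must sum to 1")
        if self.startprob.shape != (K,):
            raise ModelError("startprob must have length K")
        if np.any(self.startprob < -1e-12) or not np.isclose(
            self.startprob.sum(), 1.0, atol=1e-8
        ):
            raise ModelError("startprob must be a distribution")
        if self.emission not in ("poisson", "negative_binomial"):
            raise ModelError("emission must be 'poisson' or 'negative_binomial'")
        if self.frame_interval <= 0:
            raise ModelError("frame_interval must be > 0")

    def stationary_distribution(self) -> np.ndarray:
        """Unique stationary distribution of ``transmat``.

        Raises ReducibleChainError when more than one closed communicating
        class exists (no unique stationary distribution).
        """
        blocks = _closed_classes(self.transmat)
        if len(blocks) > 1:
            raise ReducibleChainError(blocks)
        w, v = np.linalg.eig(self.transmat.T)
        idx = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, idx])
        pi = np.abs(pi)
        return pi / pi.sum()

    def dwell_means(self) -> np.ndarray:
        """Per-state mean dwell time in minutes, Δt / (1 − A_kk)."""
        diag = np.clip(np.diag(self.transmat), 0.0, 1.0 - 1e-15)
        return self.frame_interval / (1.0 - diag)

    def state_labels(self) -> list[str]:
        """Label states [L/H, L/H] per channel by thresholding at half the
        largest fitted mean of that channel."""
        labels = []
        thr = self.means.max(axis=0) / 2.0
        thr = np.where(thr <= 0, 0.5, thr)  # all-low channel: call everything L
        for k in range(self.n_states):
            cro = "H" if self.means[k, 0] >= thr[0] and self.means[k, 0] > 0 else "L"
            ci = "H" if self.means[k, 1] >= thr[1] and self.means[k, 1] > 0 else "L"
            labels.append(f"[{cro},{ci}]")
        return labels

    # --- flat key-value persistence -------------------------------------
    def to_text(self, path: str | Path) -> None:
        lines = [
            f"K\t{self.n_states}",
            f"frame_interval\t{self.frame_interval}",
            f"emission\t{self.emission}",
            f"dispersion\t{self.dispersion}",
        ]
        for k in range(self.n_states):
            lines.append(
                f"mean_{k}\t{float(self.means[k, 0])!r}\t{float(self.means[k, 1])!r}"
            )
        for k in range(self.n_states):
            lines.append(
                "A_%d\t%s" % (k, "\t".join(repr(float(x)) for x in self.transmat[k]))
            )
        lines.append("pi\t" + "\t".join(repr(float(x)) for x in self.startprob))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "HMMModel":
        kv = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            key, *vals = line.split("\t")
            kv[key] = vals
        K = int(kv["K"][0])
        means = np.array(
            [[float(v) for v in kv[f"mean_{k}"]] for k in range(K)]
        )
        transmat = np.array(
            [[float(v) for v in kv[f"A_{k}"]] for k in range(K)]
        )
        startprob = np.array([float(v) for v in kv["pi"]])
        return cls(
            means=means,
            transmat=transmat,
            startprob=startprob,
            frame_interval=float(kv["frame_interval"][0]),
            emission=kv["emission"][0],
            dispersion=float(kv["dispersion"][0]),
        )


def _closed_classes(A: np.ndarray) -> list[set]:
    """Closed communicating classes of the chain with transition matrix A."""
    K = A.shape[0]
    reach = (A > 1e-15) | np.eye(K, dtype=bool)
    # transitive closure (Warshall)
    for m in range(K):
        reach = reach | (reach[:, m : m + 1] & reach[m : m + 1, :])
    classes = []
    seen = set()
    for i in range(K):
        if i in seen:
            continue
        comm = {j for j in range(K) if reach[i, j] and reach[j, i]}
        seen |= comm
        closed = all(
            not reach[i, j] or j in comm for j in range(K)
        )
        if closed:
            classes.append(comm)
    return classes


def table_model(config=None) -> HMMModel:
    """HMMModel calibrated to the default generator configuration
    (emission means, dwell times and stationary targets of the reference
    four-state parameter table)."""
    from switchkin.config import GeneratorConfig
    from switchkin.synthetic.markov import build_transition_matrix

    if config is None:
        config = GeneratorConfig()
    A, pi = build_transition_matrix(
        config.dwell_means,
        config.stationary_targets,
        config.frame_interval,
    )
    return HMMModel(
        means=np.asarray(config.emission_means, dtype=float),
        transmat=A,
        startprob=pi,
        frame_interval=config.frame_interval,
        emission=config.emission_family
        if config.emission_family != "negative_binomial"
        else "negative_binomial",
        dispersion=config.nb_dispersion,
    )


#: Alias used by the CLI and docs.
default_model = table_model
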