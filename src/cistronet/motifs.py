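"""ZOOPS expectation-maximization motif discovery with a shuffle null.

A single ungapped motif (position weight matrix) is sought in a set of
upstream sequences under the zero-or-one-occurrence-per-sequence (ZOOPS)
model against a 0-order background. Significance follows the decision rule
used for regulon promoter analysis: the same discovery procedure is run on
five letter-shuffled copies of the input, and the real motif is called
significant only when its score beats the best (minimum) shuffled score.

The score is an E-value-like statistic: a chi-square tail probability of
the model-vs-background log-likelihood ratio, Bonferroni-corrected for the
number of candidate widths and start positions. It is not MEME's internal
E-value; the decision rule only ever compares the same statistic on real
versus shuffled inputs, so any monotone significance score applied
identically is faithful. Scores are handled in log10 to avoid underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2
from sklearn.base import BaseEstimator

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_LOG10 = np.log(10.0)


@dataclass
class BackgroundModel:
    """0-order base frequencies over A, C, G, T."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,):
            raise ValueError("need 4 base frequencies")
        if abs(self.freqs.sum() - 1.0) > 1e-9 or (self.freqs < 0).any():
            raise ValueError("frequencies must be nonnegative and sum to 1")

    @classmethod
    def from_dict(cls, d) -> "BackgroundModel":
        return cls(np.array([d[c] for c in ALPHABET], dtype=float))


def background_from_upstreams(sequences: Sequence[str]) -> BackgroundModel:
    """Pooled mononucleotide fractions; ambiguity codes are ignored entirely."""
    counts = np.zeros(4)
    for s in sequences:
        s = s.upper()
        for i, c in enumerate(ALPHABET):
            counts[i] += s.count(c)
    total = counts.sum()
    if total == 0:
        raise ValueError("no usable (ACGT) bases in input sequences")
    return BackgroundModel(counts / total)


def encode(seq: str) -> np.ndarray:
    arr = np.fromiter((_CODE.get(c, -1) for c in seq.upper()), dtype=np.int64, count=len(seq))
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def consensus_of(pwm: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in pwm.argmax(axis=1))


@dataclass
class MotifOutcome:
    """Result of motif discovery on one module's upstream set."""

    module_id: str
    pwm: np.ndarray
    log10_evalue: float
    log10_evalue_threshold: float | None = None
    n_members_with_site: int = 0
    n_members: int = 0
    site_calls: list[bool] = field(default_factory=list)

    @property
    def consensus(self) -> str:
        return consensus_of(self.pwm)

    @property
    def e_value(self) -> float:
        return 10.0 ** max(self.log10_evalue, -300.0)

    @property
    def e_value_threshold(self) -> float:
        if self.log10_evalue_threshold is None:
            raise ValueError("no shuffle threshold attached")
        return 10.0 ** max(self.log10_evalue_threshold, -300.0)

    @property
    def significant(self) -> bool:
        if self.log10_evalue_threshold is None:
            return False
        return call_module_motif(self.log10_evalue, self.log10_evalue_threshold)


def call_module_motif(real_score: float, threshold: float) -> bool:
    """Strictly smaller score than the shuffle-null threshold wins."""
    return real_score < threshold


class _ZoopsEM:
    """One EM optimization at a fixed width over pre-encoded windows."""

    def __init__(self, seqs: list[np.ndarray], width: int, background: np.ndarray,
                 pseudocount: float):
        self.W = width
        self.b = background
        self.pseudo = pseudocount
        self.n_seq = len(seqs)
        windows = []
        bounds = [0]
        self.m_per_seq = []
        for s in seqs:
            m = len(s) - width + 1
            if m < 1:
                raise ValueError(f"sequence shorter than motif width {width}")
            windows.append(np.lib.stride_tricks.sliding_window_view(s, width))
            self.m_per_seq.append(m)
            bounds.append(bounds[-1] + m)
        self.IDX = np.concatenate(windows, axis=0)       # (total_m, W)
        self.bounds = np.array(bounds)
        self.starts = self.bounds[:-1]
        self.m = np.array(self.m_per_seq, dtype=float)
        self.log_b = np.log(self.b)
        # background log-lik of each window under b (for the ratio)
        self.win_logb = self.log_b[self.IDX].sum(axis=1)
        self.null_ll = float(sum(self.log_b[s].sum() for s in seqs))

    def run(self, theta0: np.ndarray, gamma0: float = 0.5, max_iter: int = 200,
            tol: float = 1e-6) -> dict:
        theta = theta0.copy()
        gamma = gamma0
        W = self.W
        rows = np.arange(W)
        prior_alpha = self.pseudo
        prev_obj = -np.inf
        trace = []
        eps = 1e-6
        for it in range(max_iter):
            log_theta = np.log(theta)
            # log odds of a site at each window vs background
            R = log_theta[rows[:, None], self.IDX.T].sum(axis=0) - self.win_logb
            # per-sequence mixture: (1-gamma) + gamma/m * sum_j exp(R_j)
            Rmax = np.maximum.reduceat(R, self.starts)
            expR = np.exp(R - np.repeat(Rmax, np.diff(self.bounds)))
            sums = np.add.reduceat(expR, self.starts)
            # log( (1-gamma) + gamma/m * sum exp(R) ), stably
            mix = (1.0 - gamma) * np.exp(-Rmax) + (gamma / self.m) * sums
            log_mix = np.log(mix) + Rmax
            obs_ll = self.null_ll + float(log_mix.sum())
            obj = obs_ll + prior_alpha * float(np.log(theta).sum())  # Dirichlet(1+pseudo) prior
            trace.append(obj)
            if obj < prev_obj - 1e-8:
                raise RuntimeError(f"EM objective decreased at iteration {it}: {prev_obj} -> {obj}")
            # E-step responsibilities z_j = (gamma/m) exp(R_j) / mix_total, shifted by Rmax
            z = expR * np.repeat((gamma / self.m) / mix, np.diff(self.bounds))
            if abs(obj - prev_obj) < tol and it > 0:
                prev_obj = obj
                last_obs_ll = obs_ll
                break
            prev_obj = obj
            last_obs_ll = obs_ll
            # M-step
            counts = np.zeros((W, 4))
            for w in range(W):
                counts[w] = np.bincount(self.IDX[:, w], weights=z, minlength=4)
            theta = counts + self.pseudo
            theta /= theta.sum(axis=1, keepdims=True)
            q_site = np.add.reduceat(z, self.starts)
            gamma = float(np.clip(q_site.mean(), eps, 1.0 - eps))
        # final per-sequence site posteriors and best offsets
        q_site = np.add.reduceat(z, self.starts)
        offsets = []
        for i in range(self.n_seq):
            seg = z[self.bounds[i]:self.bounds[i + 1]]
            offsets.append(int(np.argmax(seg)))
        llr = last_obs_ll - self.null_ll
        return {
            "theta": theta, "gamma": gamma, "objective": prev_obj, "llr": llr,
            "site_posterior": q_site, "offsets": offsets, "trace": trace,
        }


class ZoopsMotifFinder(BaseEstimator):
    """Single-motif ZOOPS EM over a width range with seeded restarts.

    Fitted attributes: ``pwm_`` (best width's PWM), ``consensus_``,
    ``log10_evalue_`` (width/position-corrected score, smaller = stronger),
    ``site_posteriors_``, ``site_calls_`` (posterior >= posterior_threshold),
    ``site_offsets_``, ``objective_trace_`` of the winning run.
    """

    def __init__(self, width_min=6, width_max=24, n_restarts=20, pseudocount=0.1,
                 posterior_threshold=0.5, max_iter=200, tol=1e-6, seed=0):
        self.width_min = width_min
        self.width_max = width_max
        self.n_restarts = n_restarts
        self.pseudocount = pseudocount
        self.posterior_threshold = posterior_threshold
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, sequences: Sequence[str], background: BackgroundModel | None = None
            ) -> "ZoopsMotifFinder":
        if len(sequences) < 2:
            raise ValueError("need >= 2 sequences")
        seqs = [encode(s) for s in sequences]
        min_len = min(len(s) for s in seqs)
        if min_len < self.width_min:
            raise ValueError("sequences shorter than the minimum motif width")
        width_max = min(self.width_max, min_len)
        if background is None:
            background = background_from_upstreams(sequences)
        rng = np.random.default_rng(self.seed)
        widths = list(range(self.width_min, width_max + 1))
        n_widths = len(widths)
        best = None
        for width in widths:
            em = _ZoopsEM(seqs, width, background.freqs, self.pseudocount)
            total_positions = int(em.bounds[-1])
            for _ in range(self.n_restarts):
                # seed the PWM from a random window of the data
                j = int(rng.integers(0, total_positions))
                theta0 = np.full((width, 4), 0.1)
                theta0[np.arange(width), em.IDX[j]] = 0.7
                theta0 /= theta0.sum(axis=1, keepdims=True)
                res = em.run(theta0, gamma0=0.5, max_iter=self.max_iter, tol=self.tol)
                # corrected significance of the LLR against the background-only model
                df = 3 * width + 1
                log10_p = chi2.logsf(max(2.0 * res["llr"], 0.0), df) / _LOG10
                score = log10_p + np.log10(n_widths) + np.log10(total_positions)
                if best is None or score < best[0] or (
                    score == best[0] and res["objective"] > best[1]["objective"]
                ):
                    best = (float(score), res, width)
        score, res, width = best
        self.pwm_ = res["theta"]
        self.width_ = width
        self.consensus_ = consensus_of(res["theta"])
        self.log10_evalue_ = score
        self.gamma_ = res["gamma"]
        self.site_posteriors_ = res["site_posterior"]
        self.site_calls_ = [bool(q >= self.posterior_threshold) for q in res["site_posterior"]]
        self.site_offsets_ = res["offsets"]
        self.objective_trace_ = res["trace"]
        return self


def discover_motif(sequences: Sequence[str], background: BackgroundModel | None = None,
                   width_range: tuple[int, int] = (6, 24), seed: int = 0,
                   n_restarts: int = 20, **kwargs) -> ZoopsMotifFinder:
    finder = ZoopsMotifFinder(width_min=width_range[0], width_max=width_range[1],
                              n_restarts=n_restarts, seed=seed, **kwargs)
    return finder.fit(sequences, background)


def shuffle_sequences(sequences: Sequence[str], rng: np.random.Generator) -> list[str]:
    """Permute letters independently within each sequence (composition-preserving)."""
    out = []
    for s in sequences:
        chars = np.array(list(s))
        out.append("".join(chars[rng.permutation(len(chars))]))
    return out


def shuffle_evalue_threshold(sequences: Sequence[str], background: BackgroundModel | None = None,
                             n_shuffles: int = 5, seed: int = 0,
                             width_range: tuple[int, int] = (6, 24),
                             n_restarts: int = 20, **kwargs) -> float:
    """Minimum log10 score over ``n_shuffles`` letter-shuffled replicate runs."""
    rng = np.random.default_rng(seed)
    scores = []
    for s in range(n_shuffles):
        shuffled = shuffle_sequences(sequences, rng)
        finder = discover_motif(shuffled, background, width_range,
                                seed=seed + 1000 + s, n_restarts=n_restarts, **kwargs)
        scores.append(finder.log10_evalue_)
    return float(min(scores))


def write_meme_minimal(outcomes: Sequence[MotifOutcome], background: BackgroundModel, path) -> None:
    """MEME minimal text format: version line, alphabet, background, PWMs."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bf = background.freqs
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bf[0]:.3f} C {bf[1]:.3f} G {bf[2]:.3f} T {bf[3]:.3f}\n\n")
        for o in outcomes:
            w = o.pwm.shape[0]
            fh.write(f"MOTIF {o.module_id} {o.consensus}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {w} nsites= {o.n_members_with_site} "
                     f"E= {o.e_value:.3g}\n")
            for row in o.pwm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
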