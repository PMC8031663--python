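"""De novo discovery of one ungapped RNA motif by ZOOPS expectation-maximization.

The site model is ZOOPS (zero or one occurrence per sequence): a sequence of
length L either contains no site (prior 1 - lambda) or exactly one site of
width W starting at one of L - W + 1 positions (prior lambda, uniform over
starts). Site columns follow the position weight matrix theta, all other
positions follow the 0-order background theta0 estimated from the input
sequences. EM alternates soft assignment of site positions (E-step) with
re-estimation of theta and lambda from responsibility-weighted counts
(M-step, with a small background-proportional Dirichlet pseudocount). Widths
4-10 are scanned and the minimum-E-value model is reported.

Significance is an empirical, shuffle-calibrated E-value rather than an
analytic one: the fitted model's log-likelihood ratio against the
background-only model is recomputed on mononucleotide-shuffled copies of the
input (EM re-run per shuffle at the same width) and the tail probability is
Bonferroni-scaled by the number of widths scanned. The conventional 0.05
significance threshold applies.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .io import IUPAC_RNA, RNA_ALPHABET, SequenceSet

logger = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}
_PAIR_CODE = {
    frozenset("AG"): "r", frozenset("CU"): "y", frozenset("CG"): "s",
    frozenset("AU"): "w", frozenset("GU"): "k", frozenset("AC"): "m",
}


@dataclass
class ZoopsConfig:
    w_min: int = 4
    w_max: int = 10
    n_restarts: int = 20          # random starts per width
    max_substring_starts: int = 500   # cap on W-mer-seeded starts
    max_iter: int = 200
    tol: float = 1e-6             # relative objective change
    pseudocount: float = 0.01     # total Dirichlet mass, split by background
    n_shuffles: int = 200
    shuffle_substring_starts: int = 60  # start budget for each shuffled re-fit
    shuffle_restarts: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 4 <= self.w_min <= self.w_max:
            raise ValueError("need 4 <= w_min <= w_max")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class MotifModel:
    width: int
    pwm: np.ndarray                 # W x 4, rows sum to 1, columns A,C,G,U
    background: np.ndarray          # 4-vector
    lam: float                      # ZOOPS per-sequence site probability
    log_likelihood: float
    objective_trace: list[float] = field(default_factory=list)
    site_posteriors: dict[str, np.ndarray] = field(default_factory=dict)
    no_site_mass: dict[str, float] = field(default_factory=dict)
    e_value: float = float("nan")
    n_widths_scanned: int = 1
    llr: float = float("nan")       # log-likelihood ratio vs background-only
    null_z: float = float("nan")    # LLR surprise vs the shuffle null

    @property
    def consensus(self) -> str:
        return consensus_from_pwm(self.pwm)

    def best_sites(self) -> dict[str, int]:
        """Per sequence, the maximum-responsibility start position."""
        return {sid: int(np.argmax(z)) for sid, z in self.site_posteriors.items()}


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int8, count=len(seq))


def build_background(seqs: SequenceSet) -> np.ndarray:
    """Pooled 0-order nucleotide frequencies over all input sequences."""
    if len(seqs) == 0:
        raise ValueError("cannot estimate background from an empty sequence set")
    counts = np.zeros(4)
    for s in seqs.sequences.values():
        counts += np.bincount(encode(s), minlength=4)
    return counts / counts.sum()


def _content_seed(seqs: SequenceSet, salt: int) -> int:
    """RNG seed keyed to sequence content (order-invariant), < 2**31."""
    digest = zlib.crc32("\n".join(sorted(seqs.sequences.values())).encode())
    return (digest ^ (salt * 0x9E3779B1)) % (2**31 - 1)


class _WindowIndex:
    """Flattened view of all width-W windows across a sequence set."""

    def __init__(self, seqs: SequenceSet, W: int):
        ids, arrays = [], []
        for sid, s in seqs.items():
            if len(s) < W:
                raise ValueError(f"sequence {sid!r} shorter than motif width {W}")
            ids.append(sid)
            arrays.append(encode(s))
        self.ids = ids
        self.W = W
        self.n_seq = len(ids)
        m = np.array([a.size - W + 1 for a in arrays])
        self.m = m
        self.offsets = np.concatenate([[0], np.cumsum(m)[:-1]])
        win = np.empty((m.sum(), W), dtype=np.int8)
        row = 0
        for a, mi in zip(arrays, m):
            idx = np.arange(W)[None, :] + np.arange(mi)[:, None]
            win[row:row + mi] = a[idx]
            row += mi
        self.windows = win
        self.seq_base_counts = np.stack([np.bincount(a, minlength=4) for a in arrays])

    def distinct_wmers(self) -> np.ndarray:
        return np.unique(self.windows, axis=0)


def _em_batch(
    win: _WindowIndex,
    background: np.ndarray,
    theta_inits: np.ndarray,   # S x W x 4
    lam_inits: np.ndarray,     # S
    config: ZoopsConfig,
) -> tuple[np.ndarray, float, float, list[float]]:
    """Run EM from every start simultaneously; returns the best start's
    (theta, lambda, data_ll, objective_trace), best by final data
    log-likelihood. The penalized objective (likelihood plus the Dirichlet
    pseudocount prior on the PWM) is asserted non-decreasing for every
    start at every iteration, within 1e-9."""
    W = win.W
    S = theta_inits.shape[0]
    log_bg = np.log(background)
    bg_win = log_bg[win.windows].sum(axis=1)             # per-window bg log-prob
    bg_seq_total = float((win.seq_base_counts * log_bg).sum())
    pc = config.pseudocount * background                 # Dirichlet pseudocounts
    cols = np.arange(W)
    m_rep = np.repeat(win.m, win.m).astype(float)
    # one-hot window bases for the weighted-count M-step: N x W x 4
    onehot = np.zeros((win.windows.shape[0], W, 4))
    onehot[np.arange(win.windows.shape[0])[:, None], cols, win.windows] = 1.0

    theta = theta_inits.copy()
    lam = lam_inits.astype(float).copy()
    traces: list[list[float]] = [[] for _ in range(S)]
    keep_map = np.arange(S)
    prev_obj = np.full(S, -np.inf)
    data_ll = np.full(S, -np.inf)
    active = np.ones(S, dtype=bool)
    burn_in = 15  # iterations before pruning to the most promising starts
    for it in range(config.max_iter):
        log_theta = np.log(theta)                        # S x W x 4
        # per-start, per-window log odds: sum over columns of the gathered PWM
        log_ratio = log_theta[:, cols, win.windows].sum(axis=2) - bg_win
        r = (lam[:, None] / m_rep) * np.exp(log_ratio)   # S x N
        denom = (1.0 - lam)[:, None] + np.add.reduceat(r, win.offsets, axis=1)
        z = r / np.repeat(denom, win.m, axis=1)
        q = 1.0 - (1.0 - lam)[:, None] / denom           # S x n_seq
        data_ll = np.log(denom).sum(axis=1) + bg_seq_total
        obj = data_ll + (pc * log_theta).sum(axis=(1, 2))
        if np.any(obj + 1e-9 < prev_obj):
            worst = int(np.argmax(prev_obj - obj))
            raise AssertionError(
                f"EM objective decreased: {prev_obj[worst]} -> {obj[worst]}"
            )
        for s in np.flatnonzero(active):
            traces[keep_map[s]].append(float(obj[s]))
        newly_done = active & (prev_obj > -np.inf) & (
            np.abs(obj - prev_obj) <= config.tol * np.abs(prev_obj))
        active &= ~newly_done
        prev_obj = obj
        if not active.any():
            break
        # M-step
        counts = np.einsum("sn,njb->sjb", z, onehot)
        theta = (counts + pc) / (z.sum(axis=1)[:, None, None] + pc.sum())
        lam = np.clip(q.mean(axis=1), 1e-6, 1.0 - 1e-6)
        if it == burn_in - 1 and len(data_ll) > 25:
            # keep only the most promising starts (stable order, deterministic)
            k = max(10, len(data_ll) // 10)
            top = np.sort(np.argsort(-data_ll, kind="stable")[:k])
            theta, lam = theta[top], lam[top]
            prev_obj, data_ll, active = prev_obj[top], data_ll[top], active[top]
            keep_map = keep_map[top]
    best = int(np.argmax(data_ll))
    return theta[best], float(lam[best]), float(data_ll[best]), traces[keep_map[best]]


def _seed_theta(wmer: np.ndarray, background: np.ndarray, match_p: float = 0.55) -> np.ndarray:
    W = wmer.size
    theta = np.tile((1.0 - match_p) * background, (W, 1))
    theta[np.arange(W), wmer] += match_p
    return theta / theta.sum(axis=1, keepdims=True)


def zoops_em(
    seqs: SequenceSet,
    W: int,
    background: np.ndarray | None = None,
    config: ZoopsConfig | None = None,
    *,
    substring_cap: int | None = None,
    n_random: int | None = None,
) -> MotifModel:
    """Fit the width-W ZOOPS motif model, best of many EM starts.

    Starts are one seeded start per distinct W-mer observed in the data
    (sampled down to a cap with an RNG keyed to sequence content, so the
    result is invariant to input order) plus ``n_restarts`` random starts.
    Deterministic given ``config.seed``. Raises if any sequence is shorter
    than W (naming it).
    """
    config = config or ZoopsConfig()
    config.validate()
    if background is None:
        background = build_background(seqs)
    background = np.asarray(background, float)
    win = _WindowIndex(seqs, W)

    cap = substring_cap if substring_cap is not None else config.max_substring_starts
    n_rand = n_random if n_random is not None else config.n_restarts
    rng = np.random.default_rng(_content_seed(seqs, config.seed + W))

    wmers = win.distinct_wmers()
    if len(wmers) > cap:
        pick = rng.choice(len(wmers), size=cap, replace=False)
        wmers = wmers[np.sort(pick)]

    inits = [_seed_theta(wmer, background) for wmer in wmers]
    lams = [0.5] * len(inits)
    for _ in range(n_rand):
        theta0 = rng.dirichlet(np.ones(4), size=W)
        theta0 = np.clip(theta0, 1e-6, None)
        theta0 /= theta0.sum(axis=1, keepdims=True)
        inits.append(theta0)
        lams.append(float(rng.uniform(0.2, 0.8)))
    theta, lam, data_ll, trace = _em_batch(
        win, background, np.stack(inits), np.array(lams), config)

    # final E-step bookkeeping for site posteriors
    log_theta = np.log(theta)
    log_ratio = log_theta[np.arange(W), win.windows].sum(axis=1) - \
        np.log(background)[win.windows].sum(axis=1)
    r = (lam / np.repeat(win.m, win.m)) * np.exp(log_ratio)
    denom = (1.0 - lam) + np.add.reduceat(r, win.offsets)
    z = r / np.repeat(denom, win.m)
    posts = {
        sid: z[o:o + mi]
        for sid, o, mi in zip(win.ids, win.offsets, win.m)
    }
    no_site = {sid: float((1.0 - lam) / d)
               for sid, d in zip(win.ids, denom)}
    return MotifModel(
        width=W, pwm=theta, background=background, lam=lam,
        log_likelihood=data_ll, objective_trace=trace,
        site_posteriors=posts, no_site_mass=no_site,
    )


def _shuffle_set(seqs: SequenceSet, rng: np.random.Generator) -> SequenceSet:
    """Mononucleotide shuffle: permute the letters within each sequence."""
    out = {}
    for sid, s in seqs.items():
        arr = np.frombuffer(s.encode(), dtype="S1")
        out[sid] = b"".join(rng.permutation(arr)).decode()
    return SequenceSet(out)


def background_loglik(seqs: SequenceSet, background: np.ndarray) -> float:
    log_bg = np.log(np.asarray(background, float))
    return float(sum((np.bincount(encode(s), minlength=4) * log_bg).sum()
                     for s in seqs.sequences.values()))


def motif_evalue(
    model: MotifModel,
    seqs: SequenceSet,
    n_shuffles: int = 200,
    seed: int = 0,
    *,
    config: ZoopsConfig | None = None,
    n_widths: int = 1,
) -> float:
    """Empirical shuffle-calibrated E-value of a fitted motif.

    The observed statistic is the ZOOPS log-likelihood ratio against the
    background-only model. Each of ``n_shuffles`` mononucleotide-shuffled
    copies of the input is re-fit at the same width (with a reduced start
    budget) and the E-value is the add-one tail probability multiplied by
    ``n_widths`` (Bonferroni over the widths scanned). The reporting floor
    is n_widths / (1 + n_shuffles).
    """
    config = config or ZoopsConfig()
    if n_shuffles < 20:
        logger.warning("motif_evalue: n_shuffles=%d is small; the E-value floor "
                       "is %.3g", n_shuffles, n_widths / (1 + n_shuffles))
    observed = model.log_likelihood - background_loglik(seqs, model.background)
    rng = np.random.default_rng(np.random.SeedSequence([seed, model.width, 7]))
    null_stats = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuf = _shuffle_set(seqs, rng)
        refit = zoops_em(
            shuf, model.width, model.background, config,
            substring_cap=config.shuffle_substring_starts,
            n_random=config.shuffle_restarts,
        )
        null_stats[i] = refit.log_likelihood - background_loglik(shuf,
                                                                 model.background)
    exceed = int((null_stats >= observed).sum())
    model.llr = float(observed)
    sd = float(null_stats.std(ddof=1))
    model.null_z = float((observed - null_stats.mean()) / sd) if sd > 0 else 0.0
    return n_widths * (1 + exceed) / (1 + n_shuffles)


def discover(seqs: SequenceSet, config: ZoopsConfig | None = None) -> MotifModel:
    """Width scan w_min..w_max; returns the minimum-E-value model.

    Per width, sequences shorter than W are dropped (logged); ties in
    E-value break toward higher log-likelihood, then smaller width.
    """
    config = config or ZoopsConfig()
    config.validate()
    background = build_background(seqs)
    widths = [w for w in range(config.w_min, config.w_max + 1)
              if any(len(s) >= w for s in seqs.sequences.values())]
    if not widths:
        raise ValueError("no feasible motif width for these sequences")
    candidates: list[MotifModel] = []
    for W in widths:
        usable_ids = [sid for sid, s in seqs.items() if len(s) >= W]
        dropped = [sid for sid in seqs if sid not in set(usable_ids)]
        if dropped:
            logger.info("discover: width %d drops %d too-short sequence(s): %s",
                        W, len(dropped), dropped[:5])
        sub = seqs.subset(usable_ids)
        model = zoops_em(sub, W, background, config)
        model.e_value = motif_evalue(model, sub, config.n_shuffles, config.seed,
                                     config=config, n_widths=len(widths))
        model.n_widths_scanned = len(widths)
        candidates.append(model)
    # The empirical E-value saturates at its reporting floor, so candidates
    # that are all "maximally significant" tie; among those the
    # null-normalized surprise of the LLR discriminates widths (it peaks at
    # the true width, while the raw likelihood always favours wider models),
    # then higher likelihood, then smaller width.
    candidates.sort(key=lambda m: (m.e_value, -m.null_z, -m.log_likelihood,
                                   m.width))
    return candidates[0]


def consensus_from_pwm(pwm: np.ndarray) -> str:
    """Degenerate IUPAC consensus: per column, a single uppercase base when
    its probability is >= 0.5 and >= 2x the runner-up; a lowercase two-base
    code when the top two sum to >= 0.75; otherwise 'n'."""
    out = []
    for row in np.asarray(pwm, float):
        order = np.argsort(row)[::-1]
        top, second = row[order[0]], row[order[1]]
        if top >= 0.5 and top >= 2 * second:
            out.append(RNA_ALPHABET[order[0]])
        elif top + second >= 0.75:
            pair = frozenset(RNA_ALPHABET[i] for i in order[:2])
            out.append(_PAIR_CODE[pair])
        else:
            out.append("n")
    return "".join(out)


def consensus_agreement(a: str, b: str) -> int:
    """Number of aligned positions whose IUPAC base sets intersect (equal
    lengths required)."""
    if len(a) != len(b):
        raise ValueError("consensus strings differ in length")
    return sum(
        bool(set(IUPAC_RNA[x.upper()]) & set(IUPAC_RNA[y.upper()]))
        for x, y in zip(a, b)
    )


def best_overlap_agreement(found: str, planted: str) -> int:
    """Maximum consensus agreement over all ungapped offsets of the shorter
    string against the longer one."""
    short, long_ = sorted((found, planted), key=len)
    best = 0
    for off in range(len(long_) - len(short) + 1):
        best = max(best, consensus_agreement(short, long_[off:off + len(short)]))
    return best


# ---------------------------------------------------------------------------
# text serialization (consumed by the scanner)


def model_to_text(model: MotifModel) -> str:
    lines = [
        f"width\t{model.width}",
        f"lambda\t{model.lam:.6f}",
        "background\t" + "\t".join(f"{v:.6f}" for v in model.background),
        "consensus\t" + model.consensus,
        f"e_value\t{model.e_value:.6g}",
        "pwm\tA\tC\tG\tU",
    ]
    for row in model.pwm:
        lines.append("\t" + "\t".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"


def model_from_text(text: str) -> MotifModel:
    fields: dict[str, list[str]] = {}
    pwm_rows: list[list[float]] = []
    in_pwm = False
    for line in text.strip().splitlines():
        parts = line.split("\t")
        if parts[0] == "pwm":
            in_pwm = True
            continue
        if in_pwm:
            pwm_rows.append([float(v) for v in parts if v])
        else:
            fields[parts[0]] = parts[1:]
    pwm = np.array(pwm_rows)
    model = MotifModel(
        width=int(fields["width"][0]),
        pwm=pwm,
        background=np.array([float(v) for v in fields["background"]]),
        lam=float(fields["lambda"][0]),
        log_likelihood=float("nan"),
        e_value=float(fields["e_value"][0]),
    )
    if pwm.shape != (model.width, 4):
        raise ValueError("PWM shape inconsistent with declared width")
    return model
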