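"""Allelic copy number and clonal sample-fraction estimation (step three).

The tumor is modeled as a mixture of normal diploid cells and K clonal cell
subsets with sample fractions ``f_1 > ... > f_K``. Depth ratios between the
tumor and the pooled controls are segmented with circular binary
segmentation; at most one clone carries a copy-number alteration (total
copies N, minor-allele copies M) per segment, the remaining cells being
diploid there.

Given ``(f, W, C)`` — sample fractions, beta-binomial dispersion weights and
a depth-centering constant — the expectation step inverts segment depth
ratios and heterozygous B-allele fractions into per-clone integer copy
states, picks the most likely altered clone per segment and the most likely
clone per somatic variant. The maximization step then adjusts ``(f, W, C)``
by bounded Nelder-Mead on a penalized mean log-likelihood combining Poisson
exon-depth terms, beta-binomial allele-fraction terms for heterozygous and
somatic variants, and priors on copy states and sample fractions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import beta as beta_dist
from scipy.stats import betabinom, norm, poisson

logger = logging.getLogger("lumoscall")

_EPS_PHI = 1e-6
_EPS_POIS = 1e-3
F_BOUNDS = (0.01, 0.99)
W_BOUNDS = (2.0, 1e4)
C_BOUNDS = (0.5, 4.0)


# ---------------------------------------------------------------------------
# Elementary model quantities
# ---------------------------------------------------------------------------

def round_half_away(x):
    """Round half away from zero (avoids banker's rounding at .5 ties)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def expected_somatic_af(f: float, n_total: float, m_minor: float) -> float:
    """Expected somatic allele fraction ``f(N-M) / (fN + 2(1-f))``.

    The variant is assumed to ride on the non-minor copies of the altered
    clone, diluted by the diploid non-clone cells.
    """
    if n_total < 0 or not 0 <= m_minor <= max(n_total, 0):
        raise ValueError(f"need 0 <= M <= N, got N={n_total}, M={m_minor}")
    denom = f * n_total + 2.0 * (1.0 - f)
    if denom == 0.0:
        logger.warning("degenerate somatic AF (f=%s, N=%s): returning 0", f, n_total)
        return 0.0
    return float(np.clip(f * (n_total - m_minor) / denom, 0.0, 1.0))


def expected_het_af(f: float, n_total: float, m_minor: float) -> float:
    """Expected minor-band germline het allele fraction ``fM/N + (1-f)/2``."""
    if n_total <= 0:
        logger.debug("expected_het_af with N=0: dropping M/N term")
        return float(np.clip((1.0 - f) / 2.0, 0.0, 1.0))
    return float(np.clip(f * m_minor / n_total + (1.0 - f) / 2.0, 0.0, 1.0))


def expected_exon_depth(f: float, n_total: float, c: float, r_cn) -> np.ndarray:
    """Expected tumor exon depth ``(f N + 2(1-f)) R_Cn / C``."""
    if c <= 0:
        raise ValueError("centering parameter C must be positive")
    r_cn = np.asarray(r_cn, dtype=float)
    return (f * r_cn * n_total + 2.0 * (1.0 - f) * r_cn) / c


def copy_state_for_clone(f: float, c: float, mean_ratio: float,
                         het_minor_fraction: float | None) -> tuple[int, int]:
    """Invert a segment's depth ratio and het minor-allele fraction into an
    integer copy state ``(N, M)`` for a clone with sample fraction ``f``.

    ``N = max(round((C * ratio - 2(1-f)) / f), 0)``; ``M`` inverts the het
    band expectation ``phi = fM/N + (1-f)/2`` and is clamped to
    ``[0, floor(N/2)]``. With no hets in the segment M defaults to the most
    diploid-like minor state ``floor(N/2)``.
    """
    if f <= 0:
        raise ValueError("f must be positive")
    if mean_ratio <= 0:
        return 0, 0
    n = int(max(round_half_away((c * mean_ratio - 2.0 * (1.0 - f)) / f), 0.0))
    if n == 0:
        return 0, 0
    if het_minor_fraction is None:
        return n, n // 2
    m = round_half_away(n * (het_minor_fraction - (1.0 - f) / 2.0) / f)
    m = int(np.clip(m, 0, n // 2))
    return n, m


def expected_somatic_af_piecewise(i: int, f: np.ndarray, i_j: int,
                                  n_j: int, m_j: int) -> float:
    """Expected somatic AF for clone ``i`` in a segment whose copy
    alteration belongs to clone ``i_j`` (all indices 0-based).

    A variant in the altered clone itself sits on the major allele; variants
    in other clones occupy exactly one copy.
    """
    f_i = float(f[i])
    f_ij = float(f[i_j])
    if i == i_j:
        return expected_somatic_af(f_ij, n_j, m_j)
    if n_j > 0:
        return float(np.clip(f_i / (f_ij * n_j + 2.0 * (1.0 - f_ij)), 0.0, 1.0))
    return float(np.clip(min(1.0 - f_ij, f_i) / 2.0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Likelihood primitives
# ---------------------------------------------------------------------------

def betabinomial_logpmf(k, n, a, b) -> np.ndarray:
    """Log beta-binomial pmf; ``pmf(0, 0, ., .) = 1`` by convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("beta-binomial shape parameters must be positive")
    k = np.asarray(k)
    n = np.asarray(n)
    out = betabinom.logpmf(k, n, a, b)
    return np.where(n == 0, np.where(k == 0, 0.0, -np.inf), out)


def betabinomial_pmf(k, n, a, b):
    return np.exp(betabinomial_logpmf(k, n, a, b))


def exon_depth_loglik(r_t, r_hat) -> np.ndarray:
    """Poisson log-likelihood of rounded tumor exon depths around the
    rounded expectation; zero expectations are floored at a small mean."""
    mean = round_half_away(np.asarray(r_hat, dtype=float))
    mean = np.maximum(mean, _EPS_POIS)
    return poisson.logpmf(round_half_away(np.asarray(r_t, dtype=float)), mean)


def _clamp_phi(phi):
    return np.clip(phi, _EPS_PHI, 1.0 - _EPS_PHI)


def het_af_loglik(k, n, w: float, phi) -> np.ndarray:
    """Beta-binomial log-likelihood of het minor-allele counts at
    expectation ``phi`` with concentration ``w``."""
    phi = _clamp_phi(np.asarray(phi, dtype=float))
    return betabinomial_logpmf(k, n, w * phi, w * (1.0 - phi))


def het_band_mixture_loglik(k, n, w, phi_minor) -> np.ndarray:
    """Log-likelihood of raw het B counts under the two parental bands.

    The B allele sits on the minor or the major parental copies with equal
    probability, so the expected B fraction is ``phi`` or ``1 - phi``; the
    likelihood is the symmetric 50/50 beta-binomial mixture. Unlike folding
    the counts to ``min(R_B, R_A)``, the mixture is unbiased at phi = 1/2.
    """
    phi = _clamp_phi(np.asarray(phi_minor, dtype=float))
    lo = betabinomial_logpmf(k, n, w * phi, w * (1.0 - phi))
    hi = betabinomial_logpmf(k, n, w * (1.0 - phi), w * phi)
    return np.logaddexp(lo, hi) - math.log(2.0)


def somatic_af_loglik(k, n, w, phi, folded: bool = True) -> np.ndarray:
    """Beta-binomial log-likelihood of somatic B counts.

    By default the shape parameters are folded so the expectation is the
    minor of ``phi`` and ``1 - phi``; ``folded=False`` uses ``phi`` as is.
    """
    phi = _clamp_phi(np.asarray(phi, dtype=float))
    w = np.asarray(w, dtype=float)
    a, b = w * phi, w * (1.0 - phi)
    if folded:
        a, b = np.minimum(a, b), np.maximum(a, b)
    return betabinomial_logpmf(k, n, a, b)


def f_prior_logpdf(f, f_pi: float, alpha_pi: float) -> np.ndarray:
    """Log density of the Beta prior on sample fractions, parameterized so
    its mode is ``f_pi``: second shape ``(alpha-1)/f_pi - alpha + 2``."""
    if alpha_pi <= 1.0:
        raise ValueError("alpha_pi must be > 1")
    b = (alpha_pi - 1.0) / f_pi - alpha_pi + 2.0
    return beta_dist.logpdf(np.asarray(f, dtype=float), alpha_pi, b)


def f_prior_density(f, f_pi: float, alpha_pi: float):
    return np.exp(f_prior_logpdf(f, f_pi, alpha_pi))


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------

def _best_arc(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Maximal |t| circular arc statistic: arc mean vs complement mean."""
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    total = s[-1]
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        sd = 1e-12
    best = (0.0, 0, n)
    i_idx, j_idx = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    w = j_idx - i_idx
    valid = (w >= min_width) & ((n - w) >= min_width)
    if not valid.any():
        return best
    arc = s[j_idx] - s[i_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (arc / w - (total - arc) / (n - w)) / (sd * np.sqrt(1.0 / w + 1.0 / (n - w)))
    t = np.where(valid, np.abs(t), 0.0)
    flat = int(np.argmax(t))
    i, j = np.unravel_index(flat, t.shape)
    return float(t[i, j]), int(i), int(j)


def _arc_p_value(t_stat: float, n: int, min_width: int) -> float:
    """Bonferroni-corrected two-sided normal tail bound over all tested arcs."""
    m = max(1, n * (n - 1) // 2)
    p0 = 2.0 * float(norm.sf(abs(t_stat)))
    return min(1.0, m * p0)


def cbs_segment(ratios: np.ndarray, alpha: float = 1e-5,
                min_width: int = 5) -> list[tuple[int, int]]:
    """Circular binary segmentation of a (log) ratio profile.

    Recursively finds the most significant circular arc; a change is accepted
    when its Bonferroni-bounded p-value falls below ``alpha``. Returns
    contiguous, non-overlapping ``(start, end)`` index spans covering the
    profile. Profiles shorter than 10 points are returned whole.
    """
    n = len(ratios)
    if n < 10:
        if n > 0:
            logger.warning("only %d exons: skipping segmentation", n)
        return [(0, n)] if n else []
    segments: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        x = np.asarray(ratios[lo:hi], dtype=float)
        n_x = hi - lo
        if n_x < 2 * min_width:
            segments.append((lo, hi))
            return
        t_stat, i, j = _best_arc(x, min_width)
        if t_stat <= 0 or _arc_p_value(t_stat, n_x, min_width) >= alpha:
            segments.append((lo, hi))
            return
        cuts = sorted({lo, lo + i, lo + j, hi})
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b > a:
                recurse(a, b)

    recurse(0, n)
    segments.sort()
    return segments


def segment_depth_ratio(exons: pd.DataFrame, alpha_seg: float = 1e-5,
                        min_width: int = 5) -> np.ndarray:
    """Segment tumor/control depth ratios per chromosome.

    ``exons`` needs chrom, tumor_depth, control_depth (genomic order).
    Returns a per-exon integer segment id. Exons with zero control depth
    must be dropped beforehand.
    """
    if (exons["control_depth"] <= 0).any():
        raise ValueError("drop zero control-depth exons before segmentation")
    seg_id = np.full(len(exons), -1, dtype=int)
    next_id = 0
    log_ratio = np.log2(exons["tumor_depth"].to_numpy()
                        / exons["control_depth"].to_numpy() + 1e-9)
    for chrom in exons["chrom"].unique():
        idx = np.flatnonzero((exons["chrom"] == chrom).to_numpy())
        for lo, hi in cbs_segment(log_ratio[idx], alpha_seg, min_width):
            seg_id[idx[lo:hi]] = next_id
            next_id += 1
    return seg_id


# ---------------------------------------------------------------------------
# Clone model and EM fit
# ---------------------------------------------------------------------------

@dataclass
class CloneModel:
    """Fitted clonal mixture: fractions ``f`` (descending), dispersion ``W``
    per clone, and depth-centering ``C``."""

    f: np.ndarray
    W: np.ndarray
    C: float

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if np.any(self.f <= 0) or np.any(self.f >= 1):
            raise ValueError("clone fractions must lie in (0, 1)")
        if np.any(self.W <= 0) or self.C <= 0:
            raise ValueError("W and C must be positive")

    @property
    def K(self) -> int:
        return len(self.f)

    def sort_identifiable(self) -> None:
        order = np.argsort(-self.f)
        self.f = self.f[order]
        self.W = self.W[order]
        if len(self.f) > 1 and np.min(np.abs(np.diff(self.f))) < 1e-3:
            logger.warning("duplicate clone fractions after M-step: %s", self.f)


@dataclass
class Segment:
    """One depth segment with its fitted copy state and clone assignment."""

    chrom: str
    start: int
    end: int
    exon_lo: int
    exon_hi: int
    mean_ratio: float
    het_minor_fraction: float | None
    clone: int = 1           # 1-based index of the altered clone
    f: float = 0.0
    n_total: int = 2
    m_minor: int = 1
    n_exons: int = 0
    n_hets: int = 0
    phi_het: float = 0.5
    per_clone_states: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_altered(self) -> bool:
        return (self.n_total, self.m_minor) != (2, 1)


def assign_segment_clone(model: CloneModel, seg: Segment,
                         exon_rt: np.ndarray, exon_rc: np.ndarray,
                         het_k: np.ndarray, het_n: np.ndarray) -> int:
    """Most likely altered clone for a segment (0-based index).

    Scores each clone by the mean exon-depth log-likelihood under its
    implied copy state plus (when the segment contains hets) the mean het
    allele-fraction log-likelihood; ties break toward the larger ``f``.
    """
    scores = np.empty(model.K)
    for i in range(model.K):
        n_i, m_i = seg.per_clone_states[i]
        r_hat = expected_exon_depth(model.f[i], n_i, model.C, exon_rc)
        score = float(np.mean(exon_depth_loglik(exon_rt, r_hat)))
        if len(het_k) > 0:
            phi = expected_het_af(model.f[i], n_i, m_i)
            score += float(np.mean(het_band_mixture_loglik(het_k, het_n,
                                                           model.W[i], phi)))
        scores[i] = score
    return int(np.argmax(scores))  # f sorted desc -> first max is largest f


def assign_variant_clone(model: CloneModel, seg: Segment,
                         r_b: int, r_t: int, folded: bool = True) -> tuple[int, float]:
    """Most likely clone (0-based) and its expected AF for one somatic
    variant inside ``seg``."""
    i_j = seg.clone - 1
    lls = np.empty(model.K)
    phis = np.empty(model.K)
    for i in range(model.K):
        phis[i] = expected_somatic_af_piecewise(i, model.f, i_j,
                                                seg.n_total, seg.m_minor)
        lls[i] = somatic_af_loglik(r_b, r_t, model.W[i], phis[i], folded)
    best = int(np.argmax(lls))
    return best, float(phis[best])


def _fold_het_counts(r_b: np.ndarray, r_t: np.ndarray) -> np.ndarray:
    """Minor-allele counts: the B allele is the minor or major parental
    allele with equal probability, so het bands fold around 1/2."""
    return np.minimum(r_b, r_t - r_b)


class _EMData:
    """Flat arrays for fast objective evaluation."""

    def __init__(self, exons: pd.DataFrame, hets: pd.DataFrame,
                 somatics: pd.DataFrame, seg_id: np.ndarray):
        self.exon_rt = exons["tumor_depth"].to_numpy(dtype=float)
        self.exon_rc = exons["control_depth"].to_numpy(dtype=float)
        self.seg_id = seg_id
        self.het_k_raw = hets["r_b"].to_numpy(dtype=int)
        self.het_k = _fold_het_counts(self.het_k_raw,
                                      hets["r_t"].to_numpy(dtype=int))
        self.het_n = hets["r_t"].to_numpy(dtype=int)
        self.het_seg = seg_id[hets["exon_idx"].to_numpy(dtype=int)]
        self.som_k = somatics["r_b"].to_numpy(dtype=int)
        self.som_n = somatics["r_t"].to_numpy(dtype=int)
        self.som_seg = seg_id[somatics["exon_idx"].to_numpy(dtype=int)] \
            if len(somatics) else np.empty(0, dtype=int)
        self.X = len(self.exon_rt)
        self.V = len(self.het_k)
        self.Y = len(self.som_k)


def _build_segments(exons: pd.DataFrame, data: _EMData,
                    seg_id: np.ndarray) -> list[Segment]:
    segments = []
    for sid in np.unique(seg_id):
        mask = seg_id == sid
        idx = np.flatnonzero(mask)
        lo, hi = idx[0], idx[-1] + 1
        rt = data.exon_rt[mask]
        rc = data.exon_rc[mask]
        hmask = data.het_seg == sid
        hk, hn = data.het_k[hmask], data.het_n[hmask]
        phi_hat = float(hk.sum() / hn.sum()) if hn.sum() > 0 else None
        segments.append(Segment(
            chrom=str(exons["chrom"].iloc[lo]),
            start=int(exons["start"].iloc[lo]), end=int(exons["end"].iloc[hi - 1]),
            exon_lo=int(lo), exon_hi=int(hi),
            mean_ratio=float(rt.mean() / rc.mean()),
            het_minor_fraction=phi_hat,
            n_exons=int(mask.sum()), n_hets=int(hmask.sum()),
        ))
    return segments


def _e_step(model: CloneModel, data: _EMData, segments: list[Segment],
            folded: bool) -> dict:
    """Update copy states, segment clones and variant clones in place;
    return the per-site state arrays needed by the objective."""
    som_clone = np.zeros(data.Y, dtype=int)
    som_phi = np.zeros(data.Y)
    for sid, seg in enumerate(segments):
        seg.per_clone_states = [
            copy_state_for_clone(model.f[i], model.C, seg.mean_ratio,
                                 seg.het_minor_fraction)
            for i in range(model.K)
        ]
        emask = data.seg_id == sid
        hmask = data.het_seg == sid
        i_j = assign_segment_clone(model, seg, data.exon_rt[emask],
                                   data.exon_rc[emask],
                                   data.het_k_raw[hmask], data.het_n[hmask])
        seg.clone = i_j + 1
        seg.f = float(model.f[i_j])
        seg.n_total, seg.m_minor = seg.per_clone_states[i_j]
        seg.phi_het = expected_het_af(model.f[i_j], seg.n_total, seg.m_minor)
        smask = data.som_seg == sid
        for s in np.flatnonzero(smask):
            som_clone[s], som_phi[s] = assign_variant_clone(
                model, seg, int(data.som_k[s]), int(data.som_n[s]), folded)
    return {"som_clone": som_clone, "som_phi": som_phi}


def _state_arrays(data: _EMData, segments: list[Segment], som_clone: np.ndarray):
    seg_clone = np.array([s.clone - 1 for s in segments], dtype=int)
    seg_n = np.array([s.n_total for s in segments], dtype=int)
    seg_m = np.array([s.m_minor for s in segments], dtype=int)
    return {
        "exon_i": seg_clone[data.seg_id],
        "exon_n": seg_n[data.seg_id],
        "exon_m": seg_m[data.seg_id],
        "het_i": seg_clone[data.het_seg],
        "het_n_cn": seg_n[data.het_seg],
        "het_m_cn": seg_m[data.het_seg],
        "som_i": som_clone,
        "som_seg_i": seg_clone[data.som_seg] if data.Y else np.empty(0, dtype=int),
        "som_n_cn": seg_n[data.som_seg] if data.Y else np.empty(0, dtype=int),
        "som_m_cn": seg_m[data.som_seg] if data.Y else np.empty(0, dtype=int),
    }


def _phi_somatic_vec(f: np.ndarray, som_i, som_seg_i, n_cn, m_cn) -> np.ndarray:
    f_i = f[som_i]
    f_ij = f[som_seg_i]
    same = som_i == som_seg_i
    denom = f_ij * n_cn + 2.0 * (1.0 - f_ij)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_same = np.where(denom > 0, f_ij * (n_cn - m_cn) / denom, 0.0)
        phi_other = np.where(n_cn > 0, f_i / denom,
                             np.minimum(1.0 - f_ij, f_i) / 2.0)
    return np.clip(np.where(same, phi_same, phi_other), 0.0, 1.0)


def _objective(f: np.ndarray, w: np.ndarray, c: float, data: _EMData,
               state: dict, config, folded: bool) -> float:
    """Penalized mean log-likelihood maximized over ``(f, W, C)``.

    Normalizer ``3X + X* + V + 2Y`` where ``X*`` counts exons in
    copy-altered segments.
    """
    cn_priors = np.asarray(config.cn_priors)
    m_priors = np.asarray(config.m_priors)
    f_e = f[state["exon_i"]]
    r_hat = (f_e * data.exon_rc * state["exon_n"] +
             2.0 * (1.0 - f_e) * data.exon_rc) / c
    ll = float(np.sum(exon_depth_loglik(data.exon_rt, r_hat)))

    f_h = f[state["het_i"]]
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_g = np.where(state["het_n_cn"] > 0,
                         f_h * state["het_m_cn"] / np.maximum(state["het_n_cn"], 1)
                         + (1.0 - f_h) / 2.0,
                         (1.0 - f_h) / 2.0)
    w_h = w[state["het_i"]]
    ll += float(np.sum(het_band_mixture_loglik(data.het_k_raw, data.het_n,
                                               w_h, phi_g)))

    altered = (state["exon_n"] != 2) | (state["exon_m"] != 1)
    x_star = int(np.sum(altered))
    if data.Y:
        phi_s = _phi_somatic_vec(f, state["som_i"], state["som_seg_i"],
                                 state["som_n_cn"], state["som_m_cn"])
        ll += float(np.sum(somatic_af_loglik(data.som_k, data.som_n,
                                             w[state["som_i"]], phi_s, folded)))
        ll += float(np.sum(f_prior_logpdf(f[state["som_i"]],
                                          config.f_pi, config.alpha_pi)))
    ll += float(np.sum(np.log(cn_priors[np.minimum(state["exon_n"], 4)])))
    ll += float(np.sum(np.log(m_priors[np.minimum(state["exon_m"], 2)])))
    if x_star:
        ll += float(np.sum(f_prior_logpdf(f[state["exon_i"]][altered],
                                          config.f_pi, config.alpha_pi)))
    denom = 3 * data.X + x_star + data.V + 2 * data.Y
    return ll / denom


def _logit(x, lo, hi):
    z = (np.asarray(x) - lo) / (hi - lo)
    z = np.clip(z, 1e-9, 1 - 1e-9)
    return np.log(z / (1 - z))


def _expit(z, lo, hi):
    return lo + (hi - lo) / (1.0 + np.exp(-z))


def _pack(f, w, c, shared_w: bool):
    w = np.atleast_1d(w)
    w_part = _logit([float(np.exp(np.mean(np.log(w))))] if shared_w else w,
                    *W_BOUNDS)
    return np.concatenate([_logit(np.asarray(f), *F_BOUNDS),
                           np.atleast_1d(w_part),
                           np.atleast_1d(_logit(c, *C_BOUNDS))])


def _unpack(theta, k, shared_w: bool):
    f = _expit(theta[:k], *F_BOUNDS)
    if shared_w:
        w = np.full(k, _expit(theta[k], *W_BOUNDS))
        c = float(_expit(theta[k + 1], *C_BOUNDS))
    else:
        w = _expit(theta[k:2 * k], *W_BOUNDS)
        c = float(_expit(theta[2 * k], *C_BOUNDS))
    return np.asarray(f), np.asarray(w), c


def _m_step(model: CloneModel, data: _EMData, state: dict, config,
            folded: bool) -> CloneModel:
    """Maximize the objective over (f, W, C) with assignments held fixed;
    never returns a worse model than the input."""
    k = model.K
    shared_w = bool(getattr(config, "shared_W", True))

    def neg(theta):
        f, w, c = _unpack(theta, k, shared_w)
        return -_objective(f, w, c, data, state, config, folded)

    best_theta = _pack(model.f, model.W, model.C, shared_w)
    best_val = neg(best_theta)
    ndim = len(best_theta)
    res = minimize(neg, best_theta, method="Nelder-Mead",
                   options={"maxiter": 150 * ndim, "xatol": 1e-4,
                            "fatol": 1e-10, "adaptive": True})
    if res.fun < best_val:
        best_theta, best_val = res.x, res.fun
    f, w, c = _unpack(best_theta, k, shared_w)
    new = CloneModel(f=f, W=w, C=c)
    new.sort_identifiable()
    return new


def _initial_models(k: int) -> list[CloneModel]:
    """Three deterministic EM starts: evenly spaced f grids, W=30, C=2."""
    grids = [np.linspace(0.75, 0.25, k), np.linspace(0.9, 0.45, k),
             np.linspace(0.5, 0.1, k)]
    if k == 1:
        grids = [np.array([0.75]), np.array([0.5]), np.array([0.25])]
    return [CloneModel(f=g.copy(), W=np.full(k, 30.0), C=2.0) for g in grids]


def fit_clone_model(exons: pd.DataFrame, hets: pd.DataFrame,
                    somatics: pd.DataFrame, config,
                    seg_id: np.ndarray | None = None,
                    init_model: CloneModel | None = None):
    """Fit clone fractions, dispersion and centering by EM.

    Parameters
    ----------
    exons : DataFrame with chrom, start, end, tumor_depth, control_depth in
        genomic order (zero control-depth exons are dropped with a warning).
    hets, somatics : DataFrames with r_b, r_t, exon_idx columns giving the
        allele counts of likely-germline-het and likely-somatic variants and
        the index of their enclosing exon.
    seg_id : optional precomputed per-exon segment ids; segmented with CBS
        when omitted.

    Returns ``(model, segments, assignments, trace)`` where ``assignments``
    carries per-somatic clone indices (1-based) and expected AFs, and
    ``trace`` is the non-decreasing objective sequence.
    """
    if len(hets) == 0:
        raise ValueError("no heterozygous variants: clone model is unidentifiable")
    keep = exons["control_depth"].to_numpy() > 0
    if not keep.all():
        logger.warning("dropping %d exons with zero control depth", int((~keep).sum()))
        old_to_new = np.cumsum(keep) - 1
        exons = exons.loc[keep].reset_index(drop=True)

        def remap(df):
            idx = df["exon_idx"].to_numpy(dtype=int)
            ok = keep[idx]
            df = df.loc[ok].reset_index(drop=True)
            df["exon_idx"] = old_to_new[idx[ok]]
            return df
        hets = remap(hets)
        somatics = remap(somatics)
        if seg_id is not None:
            seg_id = seg_id[keep]

    if seg_id is None:
        seg_id = segment_depth_ratio(exons, config.alpha_seg, config.min_seg_width)
    data = _EMData(exons, hets, somatics, seg_id)
    folded = not config.unfolded_somatic_bb

    starts = _initial_models(config.K)
    if init_model is not None:
        starts = [init_model] + starts
    best = None
    for model0 in starts:
        model = model0
        segments = _build_segments(exons, data, seg_id)
        e_out = _e_step(model, data, segments, folded)
        state = _state_arrays(data, segments, e_out["som_clone"])
        obj = _objective(model.f, model.W, model.C, data, state, config, folded)
        trace = [obj]
        for _ in range(config.max_em_iters):
            model_new = _m_step(model, data, state, config, folded)
            e_new = _e_step(model_new, data, segments, folded)
            state_new = _state_arrays(data, segments, e_new["som_clone"])
            obj_new = _objective(model_new.f, model_new.W, model_new.C,
                                 data, state_new, config, folded)
            if obj_new < trace[-1] - 1e-9:
                # hard-assignment update would lower the objective: keep the
                # previous state and stop (generalized-EM safeguard)
                e_new = _e_step(model, data, segments, folded)
                break
            model, state, e_out = model_new, state_new, e_new
            improved = obj_new - trace[-1]
            trace.append(max(obj_new, trace[-1]))
            if improved < config.em_tol:
                break
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], model, [s for s in segments], e_out, trace,
                    [(s.clone, s.n_total, s.m_minor, s.f, s.phi_het,
                      s.per_clone_states) for s in segments])

    _, model, segments, e_out, trace, seg_state = best
    for seg, (clone, n_t, m_m, f_v, phi, states) in zip(segments, seg_state):
        seg.clone, seg.n_total, seg.m_minor, seg.f, seg.phi_het = \
            clone, n_t, m_m, f_v, phi
        seg.per_clone_states = states
    assignments = pd.DataFrame({
        "clone": e_out["som_clone"] + 1,
        "expected_af": e_out["som_phi"],
    })
    return model, segments, assignments, trace
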