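"""Somatic variant calling: four-way posteriors and the outer loop.

Step four of the caller. Reads at a candidate site are assumed to arise from
one of four mutually exclusive models: somatic (S), germline heterozygous
(G_AB), germline homozygous reference (G_AA), or other (O). Likelihoods are
beta-binomial around the expected allele fractions implied by the fitted
clone model and the site's copy-number segment; priors combine a
cancer-database mutation count (somatic) with Hardy-Weinberg population
frequencies (germline). The caller alternates copy-number/clone fitting
(step three) with reclassification until the somatic and germline candidate
sets stabilize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import cnmodel, qc
from .cnmodel import CloneModel, Segment
from .formats_io import Config, SiteCounts
from .panel import PanelStats, panel_scores_for_sites

logger = logging.getLogger("lumoscall")

LABELS = ("SOMATIC", "GERMLINE_HET", "GERMLINE_HOM", "OTHER", "UNCALLED")


@dataclass
class CallRecord:
    """Final per-site call: four posteriors, clone assignment and quality."""

    site: SiteCounts
    p_somatic: float
    p_germline_het: float
    p_hom: float
    p_other: float
    label: str
    clone: int = 1
    expected_af: float = 0.0
    cn: int = 2
    minor_cn: int = 1
    pt: float = 0.0
    pv: float = 0.0
    tier: str = "high"
    known_germline: bool = False

    @property
    def filter_status(self) -> str:
        if self.tier == "artifact":
            return "REJECT"
        if self.tier == "low" or self.label in ("UNCALLED", "OTHER"):
            return "LowQual"
        return "PASS"


def call_priors(f_a: float, f_b: float, omega: int, config: Config,
                is_indel: bool = False) -> tuple[float, float, float, float]:
    """Model priors ``(pi_S, pi_AB, pi_AA, pi_O)`` for one site.

    ``pi_S = rho (omega + 1)`` from the cancer-database count; germline
    priors are Hardy-Weinberg scaled by ``1 - pi_S``. Sites whose population
    frequency exceeds ``F_max_somatic`` cannot be somatic.
    """
    rho = config.rho_indel if is_indel else config.rho_SNV
    pi_s = 0.0 if f_b > config.F_max_somatic else rho * (omega + 1.0)
    pi_ab = 2.0 * f_a * f_b * (1.0 - pi_s)
    pi_aa = f_a ** 2 * (1.0 - pi_s)
    pi_o = 1.0 - pi_s - pi_ab - pi_aa
    if pi_o < 0.0:
        logger.warning("pathological frequencies at prior computation; renormalizing")
        scale = (1.0 - pi_s) / (pi_ab + pi_aa)
        pi_ab *= scale
        pi_aa *= scale
        pi_o = 0.0
    return pi_s, pi_ab, pi_aa, pi_o


def model_likelihoods(site: SiteCounts, model: CloneModel, seg: Segment,
                      folded: bool = True) -> tuple[np.ndarray, int]:
    """Log-likelihoods ``(S, G_AB, G_AA, O)`` and the best somatic clone.

    ``P(D|S)`` maximizes the folded beta-binomial over clones at each
    clone's expected somatic AF; germline terms use the segment's altered
    clone state; error rates for the homozygous/other terms come from the
    mean base qualities.
    """
    i_j = seg.clone - 1
    ll_s = np.empty(model.K)
    for i in range(model.K):
        phi = cnmodel.expected_somatic_af_piecewise(i, model.f, i_j,
                                                    seg.n_total, seg.m_minor)
        ll_s[i] = cnmodel.somatic_af_loglik(site.r_b, site.r_t, model.W[i],
                                            phi, folded)
    best_i = int(np.argmax(ll_s))
    w_best = float(model.W[best_i])
    w_j = float(model.W[i_j])

    phi_g = cnmodel.expected_het_af(model.f[i_j], seg.n_total, seg.m_minor)
    phi_g = float(np.clip(phi_g, 1e-6, 1 - 1e-6))
    # the B allele may sit on either parental copy: symmetric band mixture
    ll_ab = float(cnmodel.het_band_mixture_loglik(site.r_b, site.r_t,
                                                  w_j, phi_g))
    eps_b = min(10.0 ** (-site.qb_b / 10.0), 0.5)
    ll_aa = float(cnmodel.betabinomial_logpmf(site.r_a, site.r_t,
                                              w_best * (1.0 - eps_b), w_best * eps_b))
    eps_a = min(10.0 ** (-site.qb_a / 10.0), 0.5)
    k_other = site.r_t - site.r_a - site.r_b
    ll_o = float(cnmodel.betabinomial_logpmf(k_other, site.r_t,
                                             w_best * (1.0 - eps_a), w_best * eps_a))
    return np.array([float(ll_s[best_i]), ll_ab, ll_aa, ll_o]), best_i


def somatic_posterior(log_likelihoods: np.ndarray,
                      priors: tuple[float, float, float, float]) -> np.ndarray:
    """Four-way posteriors ``(S, G_AB, G_AA, O)``; NaNs when degenerate."""
    with np.errstate(divide="ignore"):
        log_num = np.asarray(log_likelihoods) + np.log(np.asarray(priors))
    if np.all(np.isneginf(log_num)):
        return np.full(4, np.nan)
    denom = logsumexp(log_num)
    return np.exp(log_num - denom)


def classify(posteriors: np.ndarray, config: Config) -> str:
    """Label from posteriors and the somatic/germline thresholds."""
    if np.any(np.isnan(posteriors)):
        return "UNCALLED"
    p_s, p_ab, p_aa, p_o = posteriors
    if p_s >= config.T_somatic:
        return "SOMATIC"
    if p_ab >= config.T_germline:
        return "GERMLINE_HET"
    if p_aa >= config.T_germline:
        return "GERMLINE_HOM"
    if p_o >= config.T_germline:
        return "OTHER"
    return "UNCALLED"


def _diploid_fallback_segment(model: CloneModel, chrom: str, pos: int) -> Segment:
    logger.warning("site %s:%d outside all segments; treating as diploid", chrom, pos)
    seg = Segment(chrom=chrom, start=pos - 1, end=pos, exon_lo=-1, exon_hi=-1,
                  mean_ratio=1.0, het_minor_fraction=0.5)
    seg.clone = 1  # clone of max f (sorted descending)
    seg.f = float(model.f[0])
    seg.n_total, seg.m_minor = 2, 1
    seg.per_clone_states = [(2, 1)] * model.K
    return seg


def _map_sites_to_exons(sites: list[SiteCounts], exons: pd.DataFrame) -> np.ndarray:
    """Index of the exon containing each site (-1 when off target)."""
    out = np.full(len(sites), -1, dtype=int)
    for chrom in exons["chrom"].unique():
        mask = (exons["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        starts = exons["start"].to_numpy()[idx]
        ends = exons["end"].to_numpy()[idx]
        for i, s in enumerate(sites):
            if s.chrom != chrom:
                continue
            j = np.searchsorted(starts, s.pos - 1, side="right") - 1
            if j >= 0 and s.pos - 1 < ends[j]:
                out[i] = idx[j]
    return out


def _lookup_priors(sites: list[SiteCounts], priors: pd.DataFrame | None,
                   config: Config) -> pd.DataFrame:
    table: dict[tuple[str, int, str], tuple[float, int, bool]] = {}
    if priors is not None:
        for row in priors.itertuples(index=False):
            table[(str(row.chrom), int(row.pos), str(row.allele))] = (
                float(row.f_b), int(row.omega), bool(row.known_germline))
    rows = []
    for s in sites:
        default_f = config.F_p_indel if s.is_indel else config.F_p_SNV
        f_b, omega, known = table.get((s.chrom, s.pos, s.b_allele),
                                      (default_f, 0, False))
        rows.append((f_b, omega, known))
    return pd.DataFrame(rows, columns=["f_b", "omega", "known_germline"])


def call_site(site: SiteCounts, model: CloneModel, seg: Segment,
              f_b: float, omega: int, config: Config) -> tuple[np.ndarray, str, int, float]:
    """Posteriors, label, best clone (1-based) and expected AF for one site."""
    folded = not config.unfolded_somatic_bb
    lls, best_i = model_likelihoods(site, model, seg, folded)
    f_a = max(1.0 - f_b, 0.0)
    priors = call_priors(f_a, f_b, omega, config, site.is_indel)
    post = somatic_posterior(lls, priors)
    label = classify(post, config)
    phi = cnmodel.expected_somatic_af_piecewise(best_i, model.f, seg.clone - 1,
                                                seg.n_total, seg.m_minor)
    return post, label, best_i + 1, phi


def run_caller(tumor_sites: list[SiteCounts], exons: pd.DataFrame,
               priors: pd.DataFrame | None, panel: PanelStats,
               config: Config):
    """Full tumor-only calling pass.

    ``exons`` must carry chrom/start/end/tumor_depth/control_depth in
    genomic order. Returns ``(records, model, segments, report)``.

    The initial germline/somatic candidate sets are seeded from database
    frequencies (germline: F_B >= 0.01 with near-het BAF; somatic:
    F_B <= F_max_somatic); the clone model and the classification are then
    alternated until set membership stabilizes.
    """
    panel_scores = panel_scores_for_sites(panel, tumor_sites)
    qc_table = qc.run_qc(tumor_sites, panel_scores, config.pass_thresholds,
                         config.reject_thresholds, config.T_PASS)
    site_priors = _lookup_priors(tumor_sites, priors, config)
    exon_idx = _map_sites_to_exons(tumor_sites, exons)

    keep_exons = exons["control_depth"].to_numpy() > 0
    exons_kept = exons.loc[keep_exons].reset_index(drop=True)
    old_to_new = np.where(keep_exons, np.cumsum(keep_exons) - 1, -1)
    exon_idx = np.where(exon_idx >= 0, old_to_new[exon_idx], -1)
    seg_id = cnmodel.segment_depth_ratio(exons_kept, config.alpha_seg,
                                         config.min_seg_width)

    baf = np.array([s.baf for s in tumor_sites])
    r_b = np.array([s.r_b for s in tumor_sites])
    r_t = np.array([s.r_t for s in tumor_sites])
    f_b = site_priors["f_b"].to_numpy()
    high = (qc_table["tier"] == "high").to_numpy()
    usable = high & (exon_idx >= 0) & (r_t > 0)

    germline = usable & (f_b >= 0.01) & (baf >= 0.2) & (baf <= 0.8)
    somatic = usable & (f_b <= config.F_max_somatic) & (r_b > 0)
    somatic &= ~germline
    if not germline.any():
        raise ValueError("no germline heterozygous seed sites; cannot fit clone model")

    def subset(mask):
        return pd.DataFrame({
            "r_b": r_b[mask], "r_t": r_t[mask],
            "exon_idx": exon_idx[mask],
        })

    model = segments = assignments = trace = None
    n_iter = 0
    converged = False
    for n_iter in range(1, config.max_outer_iters + 1):
        model, segments, assignments, trace = cnmodel.fit_clone_model(
            exons_kept, subset(germline), subset(somatic), config,
            seg_id=seg_id, init_model=model)
        seg_of_exon = {}
        for k, seg in enumerate(segments):
            for e in range(seg.exon_lo, seg.exon_hi):
                seg_of_exon[e] = k

        labels = np.full(len(tumor_sites), "UNCALLED", dtype=object)
        for i in np.flatnonzero(usable):
            seg = segments[seg_of_exon[exon_idx[i]]]
            _, labels[i], _, _ = call_site(
                tumor_sites[i], model, seg,
                float(f_b[i]), int(site_priors["omega"].iloc[i]), config)
        new_germline = usable & (labels == "GERMLINE_HET")
        new_somatic = usable & (labels == "SOMATIC")
        if (new_germline == germline).all() and (new_somatic == somatic).all():
            converged = True
            break
        germline, somatic = new_germline, new_somatic
        if not germline.any():
            logger.warning("germline set emptied during iteration; stopping")
            break
    if not converged:
        logger.warning("outer loop did not converge in %d iterations", n_iter)

    seg_of_exon = {}
    for k, seg in enumerate(segments):
        for e in range(seg.exon_lo, seg.exon_hi):
            seg_of_exon[e] = k

    records = []
    for i, site in enumerate(tumor_sites):
        if exon_idx[i] >= 0:
            seg = segments[seg_of_exon[exon_idx[i]]]
        else:
            seg = _diploid_fallback_segment(model, site.chrom, site.pos)
        post, label, clone, phi = call_site(
            site, model, seg, float(f_b[i]),
            int(site_priors["omega"].iloc[i]), config)
        tier = str(qc_table["tier"].iloc[i])
        if tier != "high":
            label = "UNCALLED"
        p = np.nan_to_num(post, nan=0.0)
        records.append(CallRecord(
            site=site, p_somatic=float(p[0]), p_germline_het=float(p[1]),
            p_hom=float(p[2]), p_other=float(p[3]), label=label,
            clone=clone, expected_af=float(phi),
            cn=seg.n_total, minor_cn=seg.m_minor,
            pt=float(qc_table["pt"].iloc[i]), pv=float(qc_table["pv"].iloc[i]),
            tier=tier,
            known_germline=bool(site_priors["known_germline"].iloc[i]),
        ))

    report = {
        "clone_fractions": [float(x) for x in model.f],
        "W": [float(x) for x in model.W],
        "C": float(model.C),
        "outer_iterations": n_iter,
        "converged": converged,
        "objective_trace": [float(x) for x in trace],
        "n_segments": len(segments),
        "n_somatic": int(sum(r.label == "SOMATIC" for r in records)),
        "n_germline_het": int(sum(r.label == "GERMLINE_HET" for r in records)),
    }
    return records, model, segments, report
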