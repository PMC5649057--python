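"""Detection-power simulation and synthetic cohort generation.

The power simulator asks: given mean target coverage, a clone sample
fraction ``f`` and an allelic copy state ``(N, M)``, what fraction of
somatic variants would be called at default thresholds? Per-variant depths
are lognormal around the mean coverage, B-allele reads are binomial at the
expected somatic allele fraction, and each variant is scored with the
caller's four-way posterior assuming the true ``(f, N, M)`` are known
(single-clone model).

The cohort generator emulates the same generative model end to end —
control samples, exon depths, germline heterozygous sites placed by
Hardy-Weinberg from a population-frequency mixture, clonal/subclonal
somatic variants, and sequencing artifacts — with full truth bookkeeping,
so the whole pipeline can be exercised without real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import cnmodel
from .formats_io import Config, SiteCounts

logger = logging.getLogger("lumoscall")

#: Lognormal spread of per-variant depths (log-scale sd); typical exome-like
#: depth dispersion. The mean is preserved exactly: mu = ln(cov) - sigma^2/2.
DEFAULT_SIGMA_LOG = 0.5

#: Dispersion weight used when evaluating posteriors in the power simulation.
POWER_W = 50.0

#: Mean base / mapping qualities assumed for simulated clean reads (Phred).
SIM_QB = 30.0
SIM_QM = 60.0

DEFAULT_COVERAGES = (50, 100, 200, 400, 800, 1600, 3200)
DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))
#: Copy states covering losses, neutral LOH, diploid, gains and amplification.
DEFAULT_CN_STATES = ((1, 0), (2, 0), (2, 1), (3, 0), (3, 1), (4, 0), (4, 1), (4, 2))


def draw_depths(mean_coverage: float, n: int, rng: np.random.Generator,
                sigma_log: float = DEFAULT_SIGMA_LOG) -> np.ndarray:
    """Integer per-variant depths, lognormal with arithmetic mean
    ``mean_coverage``; degenerate ``sigma_log=0`` gives constant depths.
    All depths are at least 1."""
    if mean_coverage <= 0:
        raise ValueError("mean coverage must be positive")
    if sigma_log == 0.0:
        depths = np.full(n, float(mean_coverage))
    else:
        mu = np.log(mean_coverage) - sigma_log ** 2 / 2.0
        depths = rng.lognormal(mu, sigma_log, size=n)
    return np.maximum(np.rint(depths), 1.0).astype(int)


def simulate_variant_reads(mean_coverage: float, f: float, n_total: int,
                           m_minor: int, n_variants: int,
                           rng: np.random.Generator,
                           sigma_log: float = DEFAULT_SIGMA_LOG
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Paired ``(R_T, R_B)`` draws for somatic variants in state
    ``(f, N, M)``: binomial B reads at the expected somatic AF."""
    phi_s = cnmodel.expected_somatic_af(f, n_total, m_minor)
    r_t = draw_depths(mean_coverage, n_variants, rng, sigma_log)
    r_b = rng.binomial(r_t, phi_s)
    return r_t, r_b


def _power_posteriors(r_t: np.ndarray, r_b: np.ndarray, f: float,
                      n_total: int, m_minor: int, config: Config,
                      w: float = POWER_W) -> np.ndarray:
    """Vectorized somatic posterior assuming the true clone model is known
    (K=1, the condition's ``(f, N, M)``, dispersion ``w``)."""
    phi_s = np.clip(cnmodel.expected_somatic_af(f, n_total, m_minor), 1e-6, 1 - 1e-6)
    phi_g = np.clip(cnmodel.expected_het_af(f, n_total, m_minor), 1e-6, 1 - 1e-6)
    eps = 10.0 ** (-SIM_QB / 10.0)
    r_a = r_t - r_b

    a_s, b_s = min(w * phi_s, w * (1 - phi_s)), max(w * phi_s, w * (1 - phi_s))
    ll_s = cnmodel.betabinomial_logpmf(r_b, r_t, a_s, b_s)
    ll_ab = cnmodel.betabinomial_logpmf(r_b, r_t, w * phi_g, w * (1 - phi_g))
    ll_aa = cnmodel.betabinomial_logpmf(r_a, r_t, w * (1 - eps), w * eps)
    ll_o = cnmodel.betabinomial_logpmf(r_t - r_a - r_b, r_t, w * (1 - eps), w * eps)

    f_b = config.F_p_SNV
    pi_s = config.rho_SNV  # omega = 0
    f_a = 1.0 - f_b
    pi_ab = 2 * f_a * f_b * (1 - pi_s)
    pi_aa = f_a ** 2 * (1 - pi_s)
    pi_o = 1.0 - pi_s - pi_ab - pi_aa
    log_num = np.stack([
        ll_s + np.log(pi_s), ll_ab + np.log(pi_ab),
        ll_aa + np.log(pi_aa), ll_o + np.log(pi_o),
    ])
    return np.exp(log_num[0] - logsumexp(log_num, axis=0))


def detection_fraction(mean_coverage: float, f: float, n_total: int,
                       m_minor: int, config: Config,
                       rng: np.random.Generator, n_variants: int = 1000,
                       w: float = POWER_W,
                       sigma_log: float = DEFAULT_SIGMA_LOG) -> float:
    """Fraction of simulated somatic variants with ``P(S|D) >= T_somatic``."""
    r_t, r_b = simulate_variant_reads(mean_coverage, f, n_total, m_minor,
                                      n_variants, rng, sigma_log)
    post = _power_posteriors(r_t, r_b, f, n_total, m_minor, config, w)
    return float(np.mean(post >= config.T_somatic))


def power_grid(coverages=DEFAULT_COVERAGES, fractions=DEFAULT_FRACTIONS,
               cn_states=DEFAULT_CN_STATES, config: Config | None = None,
               seed: int = 0, n_variants: int = 1000,
               w: float = POWER_W) -> pd.DataFrame:
    """Detection fraction over a (coverage x fraction x copy-state) grid.

    Deterministic given ``seed``; one independent substream per condition.
    """
    if config is None:
        config = Config()
    rows = []
    root = np.random.SeedSequence(seed)
    conditions = [(c, f, n, m) for (n, m) in cn_states
                  for f in fractions for c in coverages]
    for (cov, f, n_tot, m_min), ss in zip(conditions,
                                          root.spawn(len(conditions))):
        rng = np.random.default_rng(ss)
        det = detection_fraction(cov, f, n_tot, m_min, config, rng,
                                 n_variants, w)
        rows.append((cov, f, n_tot, m_min, det))
    return pd.DataFrame(rows, columns=["coverage", "f", "N", "M", "detection"])


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentSpec:
    """Truth for one genomic segment: exon count and the copy alteration
    carried by ``clone`` (0-based; None = diploid in every clone)."""

    n_exons: int
    clone: int | None = None
    n_total: int = 2
    m_minor: int = 1


@dataclass
class SyntheticCohort:
    """A generated tumor + unmatched controls with full truth bookkeeping."""

    tumor_sites: list[SiteCounts]
    control_sites: list[list[SiteCounts]]
    normal_sites: list[SiteCounts]
    exon_depths: pd.DataFrame          # chrom/start/end/tumor_depth/control_depth/normal_depth + per-control cols
    priors: pd.DataFrame
    truth: pd.DataFrame
    clone_fractions: np.ndarray
    w_truth: float
    seg_id: np.ndarray                 # true per-exon segment index
    site_exon_idx: np.ndarray

    def write(self, outdir) -> dict[str, str]:
        """Write the cohort as the plain-text files the CLI consumes."""
        import os

        from .formats_io import write_counts, write_priors

        os.makedirs(outdir, exist_ok=True)
        paths = {"tumor": os.path.join(outdir, "tumor.counts.tsv"),
                 "priors": os.path.join(outdir, "priors.tsv"),
                 "control_depths": os.path.join(outdir, "control_depths.tsv"),
                 "tumor_depths": os.path.join(outdir, "tumor_depths.tsv"),
                 "controls": []}
        write_counts(self.tumor_sites, paths["tumor"])
        for c, sites in enumerate(self.control_sites):
            p = os.path.join(outdir, f"control_{c}.counts.tsv")
            write_counts(sites, p)
            paths["controls"].append(p)
        control_cols = [c for c in self.exon_depths.columns
                        if c.startswith("control_") and c != "control_depth"]
        self.exon_depths[["chrom", "start", "end"] + control_cols].to_csv(
            paths["control_depths"], sep="\t", index=False)
        self.exon_depths[["chrom", "start", "end", "tumor_depth"]].to_csv(
            paths["tumor_depths"], sep="\t", index=False)
        write_priors(self.priors, paths["priors"])
        return paths

    def fit_inputs(self, which: str = "truth"):
        """(exons, hets, somatics) frames for :func:`cnmodel.fit_clone_model`,
        using the true site classes."""
        t = self.truth
        mask_h = (t["true_class"] == "germline_het").to_numpy()
        mask_s = (t["true_class"] == "somatic").to_numpy()
        r_b = np.array([s.r_b for s in self.tumor_sites])
        r_t = np.array([s.r_t for s in self.tumor_sites])

        def frame(mask):
            return pd.DataFrame({
                "r_b": r_b[mask], "r_t": r_t[mask],
                "exon_idx": self.site_exon_idx[mask],
            })
        exons = self.exon_depths[["chrom", "start", "end",
                                  "tumor_depth", "control_depth"]].copy()
        return exons, frame(mask_h), frame(mask_s)


def _clean_qualities(rng, n):
    qb = np.clip(rng.normal(33.0, 1.5, n), 25.0, 40.0)
    qm = np.clip(rng.normal(58.0, 1.5, n), 45.0, 60.0)
    return qb, qm


def _artifact_qualities(rng, n):
    qb = np.clip(rng.normal(12.0, 2.0, n), 4.0, 18.0)
    qm = np.clip(rng.normal(15.0, 3.0, n), 2.0, 19.0)
    return qb, qm


def _betabinom_draw(rng, n, phi, w):
    phi = float(np.clip(phi, 1e-6, 1 - 1e-6))
    p = rng.beta(w * phi, w * (1 - phi), size=np.shape(n))
    return rng.binomial(n, p)


def synthesize_cohort(
    clone_fractions,
    segment_layout: list[SegmentSpec],
    n_hets: int = 150,
    n_somatics: int = 40,
    n_artifacts: int = 0,
    n_controls: int = 2,
    mean_coverage: float = 600.0,
    w_truth: float = 200.0,
    p_common: float = 0.8,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a full synthetic cohort with known truth.

    Exon control depths are lognormal around ``mean_coverage``; tumor exon
    depths are Poisson around the clonal-mixture expectation (centering
    C=2, so a diploid tumor matches the controls). Germline hets follow
    Hardy-Weinberg with population frequencies from a common/private
    mixture; het and somatic B counts are beta-binomial with concentration
    ``w_truth``. Artifact sites carry degraded mapping/base qualities and
    strand skew, in the controls as well (so the panel flags them).
    """
    rng = np.random.default_rng(seed)
    f = np.sort(np.asarray(clone_fractions, dtype=float))[::-1]
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("clone fractions must be in (0, 1)")

    n_exons = sum(s.n_exons for s in segment_layout)
    seg_id = np.concatenate([
        np.full(s.n_exons, k, dtype=int) for k, s in enumerate(segment_layout)
    ])
    exon_start = np.arange(n_exons) * 200
    exon_end = exon_start + 100

    control_base = rng.lognormal(np.log(mean_coverage) - 0.02, 0.2, n_exons)
    tumor_expect = np.empty(n_exons)
    for k, spec in enumerate(segment_layout):
        mask = seg_id == k
        if spec.clone is None:
            tumor_expect[mask] = control_base[mask]
        else:
            fc = f[spec.clone]
            tumor_expect[mask] = (fc * spec.n_total + 2 * (1 - fc)) \
                * control_base[mask] / 2.0
    tumor_depth = rng.poisson(tumor_expect).astype(float)
    control_draws = [rng.poisson(control_base).astype(float)
                     for _ in range(n_controls)]

    exon_depths = pd.DataFrame({
        "chrom": "1", "start": exon_start, "end": exon_end,
        "tumor_depth": tumor_depth,
        "control_depth": np.mean(control_draws, axis=0),
        "normal_depth": control_base,
    })
    for c, d in enumerate(control_draws):
        exon_depths[f"control_{c}"] = d

    def seg_of(exon):
        return segment_layout[seg_id[exon]]

    def seg_state(exon):
        spec = seg_of(exon)
        if spec.clone is None:
            return None, 2, 1
        return spec.clone, spec.n_total, spec.m_minor

    # --- place sites ------------------------------------------------------
    used_pos: set[int] = set()

    def new_site_position(exon):
        while True:
            pos = int(exon_start[exon] + rng.integers(0, 100)) + 1
            if pos not in used_pos:
                used_pos.add(pos)
                return pos

    tumor_sites: list[SiteCounts] = []
    normal_sites: list[SiteCounts] = []
    control_sites: list[list[SiteCounts]] = [[] for _ in range(n_controls)]
    priors_rows, truth_rows = [], []
    site_exon: list[int] = []

    def tumor_site_depth(exon):
        return max(int(rng.poisson(tumor_expect[exon])), 1)

    def make_counts(chrom, pos, r_t, r_b, qb, qm, skew=0.5, is_indel=False):
        r_b = int(min(r_b, r_t))
        fwd = int(rng.binomial(r_b, skew)) if r_b else 0
        return SiteCounts(
            chrom=chrom, pos=pos, ref_allele="A", b_allele="T",
            r_t=int(r_t), r_a=int(r_t - r_b), r_b=r_b,
            qb_a=float(np.clip(rng.normal(33, 1), 25, 40)), qb_b=float(qb),
            qm_a=float(np.clip(rng.normal(58, 1.5), 45, 60)), qm_b=float(qm),
            strand_b_fwd=fwd, strand_b_rev=r_b - fwd, is_indel=is_indel,
        )

    def add_control_obs(pos, exon, genotypes):
        """genotypes: per-control 'ref'|'het'|'hom' (or 'artifact')."""
        for c, g in enumerate(genotypes):
            r_t = max(int(rng.poisson(control_base[exon])), 1)
            qb, qm = _clean_qualities(rng, 1)
            if g == "ref":
                r_b = rng.binomial(r_t, 1e-3)
            elif g == "het":
                r_b = rng.binomial(r_t, 0.5)
            elif g == "hom":
                r_b = rng.binomial(r_t, 1 - 1e-3)
            else:  # artifact
                qb, qm = _artifact_qualities(rng, 1)
                r_b = rng.binomial(r_t, rng.uniform(0.05, 0.3))
            control_sites[c].append(make_counts(
                "1", pos, r_t, r_b, qb[0], qm[0],
                skew=0.97 if g == "artifact" else 0.5))

    # germline heterozygous sites (in the tumor individual)
    het_exons = rng.integers(0, n_exons, n_hets)
    for exon in het_exons:
        pos = new_site_position(exon)
        common = rng.random() < p_common
        f_b = float(np.clip(rng.beta(0.5, 0.5), 0.01, 0.99)) if common \
            else Config().F_p_SNV
        clone, n_tot, m_min = seg_state(exon)
        i_j = clone if clone is not None else 0
        f_seg = f[i_j] if clone is not None else 0.0
        phi_minor = cnmodel.expected_het_af(f_seg, n_tot, m_min) \
            if clone is not None else 0.5
        phi = phi_minor if rng.random() < 0.5 else 1.0 - phi_minor
        r_t = tumor_site_depth(exon)
        r_b = _betabinom_draw(rng, r_t, phi, w_truth)
        qb, qm = _clean_qualities(rng, 1)
        tumor_sites.append(make_counts("1", pos, r_t, r_b, qb[0], qm[0]))
        site_exon.append(exon)
        # matched normal profile (diploid het, BAF 1/2)
        r_tn = max(int(rng.poisson(control_base[exon])), 1)
        normal_sites.append(make_counts("1", pos, r_tn,
                                        rng.binomial(r_tn, 0.5), qb[0], qm[0]))
        # unmatched controls: HWE genotypes at the population frequency
        geno = []
        for _ in range(n_controls):
            u = rng.random()
            if u < f_b ** 2:
                geno.append("hom")
            elif u < f_b ** 2 + 2 * f_b * (1 - f_b):
                geno.append("het")
            else:
                geno.append("ref")
        add_control_obs(pos, exon, geno)
        if common:
            priors_rows.append(("1", pos, "T", f_b, 0, True))
        else:
            priors_rows.append(("1", pos, "T", f_b, 0, False))
        truth_rows.append(("1", pos, "germline_het", 0, 0.0, n_tot, m_min,
                           f_b, 0, not common))

    # somatic variants, cycling through clones
    for s in range(n_somatics):
        clone_idx = s % len(f)
        for _ in range(200):
            exon = int(rng.integers(0, n_exons))
            seg_clone, n_tot, m_min = seg_state(exon)
            i_j = seg_clone if seg_clone is not None else 0
            phi = cnmodel.expected_somatic_af_piecewise(
                clone_idx, f, i_j, n_tot if seg_clone is not None else 2,
                m_min if seg_clone is not None else 1)
            if phi > 0.02:
                break
        else:
            raise ValueError(
                f"cannot place a somatic variant for clone {clone_idx}: no "
                "segment gives it a detectable allele fraction")
        pos = new_site_position(exon)
        r_t = tumor_site_depth(exon)
        r_b = _betabinom_draw(rng, r_t, phi, w_truth)
        qb, qm = _clean_qualities(rng, 1)
        tumor_sites.append(make_counts("1", pos, r_t, r_b, qb[0], qm[0]))
        site_exon.append(exon)
        r_tn = max(int(rng.poisson(control_base[exon])), 1)
        normal_sites.append(make_counts("1", pos, r_tn,
                                        rng.binomial(r_tn, 1e-3), qb[0], qm[0]))
        add_control_obs(pos, exon, ["ref"] * n_controls)
        priors_rows.append(("1", pos, "T", Config().F_p_SNV, 0, False))
        truth_rows.append(("1", pos, "somatic", clone_idx + 1,
                           float(f[clone_idx]),
                           n_tot if seg_clone is not None else 2,
                           m_min if seg_clone is not None else 1,
                           Config().F_p_SNV, 0, False))

    # artifact sites: strand-skewed, low-quality, panel-flagged
    art_exons = rng.integers(0, n_exons, n_artifacts)
    for exon in art_exons:
        pos = new_site_position(exon)
        r_t = tumor_site_depth(exon)
        r_b = rng.binomial(r_t, rng.uniform(0.05, 0.3))
        qb, qm = _artifact_qualities(rng, 1)
        tumor_sites.append(make_counts("1", pos, r_t, r_b, qb[0], qm[0], skew=0.97))
        site_exon.append(exon)
        r_tn = max(int(rng.poisson(control_base[exon])), 1)
        normal_sites.append(make_counts("1", pos, r_tn,
                                        rng.binomial(r_tn, 0.1), qb[0], qm[0],
                                        skew=0.97))
        add_control_obs(pos, exon, ["artifact"] * n_controls)
        priors_rows.append(("1", pos, "T", Config().F_p_SNV, 0, False))
        truth_rows.append(("1", pos, "artifact", 0, 0.0, 2, 1,
                           Config().F_p_SNV, 0, False))

    order = np.argsort([s.pos for s in tumor_sites], kind="stable")
    tumor_sites = [tumor_sites[i] for i in order]
    normal_sites = [normal_sites[i] for i in order]
    control_sites = [[cs[i] for i in order] for cs in control_sites]
    site_exon_idx = np.asarray(site_exon)[order]
    priors = pd.DataFrame([priors_rows[i] for i in order],
                          columns=["chrom", "pos", "allele", "f_b", "omega",
                                   "known_germline"])
    truth = pd.DataFrame([truth_rows[i] for i in order],
                         columns=["chrom", "pos", "true_class", "clone", "f",
                                  "N", "M", "f_b", "omega", "is_private"])
    return SyntheticCohort(
        tumor_sites=tumor_sites, control_sites=control_sites,
        normal_sites=normal_sites, exon_depths=exon_depths, priors=priors,
        truth=truth, clone_fractions=f, w_truth=w_truth, seg_id=seg_id,
        site_exon_idx=site_exon_idx,
    )


def dilute_cohort(cohort: SyntheticCohort, d: float,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """In-silico dilution: mix tumor and matched-normal count profiles at
    tumor proportion ``d`` by binomial read thinning.

    Returns ``(exons, hets, somatics)`` ready for
    :func:`cnmodel.fit_clone_model`; the effective sample fraction of every
    clone scales by ``d``.
    """
    if not 0.0 < d <= 1.0:
        raise ValueError("dilution must be in (0, 1]")
    rng = np.random.default_rng(seed)
    exons = cohort.exon_depths[["chrom", "start", "end", "control_depth"]].copy()
    exons["tumor_depth"] = (d * cohort.exon_depths["tumor_depth"]
                            + (1 - d) * cohort.exon_depths["normal_depth"])

    t = cohort.truth
    rows = {"germline_het": [], "somatic": []}
    for site, normal, exon, cls in zip(cohort.tumor_sites, cohort.normal_sites,
                                       cohort.site_exon_idx,
                                       t["true_class"].to_numpy()):
        if cls not in rows:
            continue
        r_b = rng.binomial(site.r_b, d) + rng.binomial(normal.r_b, 1 - d)
        r_a = rng.binomial(site.r_a, d) + rng.binomial(normal.r_a, 1 - d)
        rows[cls].append((r_b, r_b + r_a, exon))
    hets = pd.DataFrame(rows["germline_het"], columns=["r_b", "r_t", "exon_idx"])
    somatics = pd.DataFrame(rows["somatic"], columns=["r_b", "r_t", "exon_idx"])
    return exons, hets, somatics
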