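"""Panel of unmatched controls: position quality scores and reference depths.

Step one of the caller. Positions that do not look diploid across a set of
unmatched control samples are treated as unreliable: at each control site we
compare a homozygous-reference model (B reads arise from base-calling error),
a heterozygous model (B fraction 0.5) and an "unreliable" model whose
likelihood is the mapping-error probability implied by the worse of the two
allele mapping qualities. The posterior probability of the unreliable model,
averaged across controls and Phred-transformed, is the position quality
score. The panel also stores per-exon mean control depths, which later serve
as the reference for tumor/control depth ratios.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .formats_io import SiteCounts

logger = logging.getLogger("lumoscall")

PANEL_FORMAT_VERSION = 1

#: Phred cap applied when the mean unreliable posterior underflows to zero.
PHRED_CAP = 250.0


def control_state_likelihoods(site: SiteCounts) -> tuple[float, float, float]:
    """Likelihood of a control site under hom-ref, het, and unreliable models.

    ``P(D|G_AA) = Binom(r_b; r_t, 10^(-qb_b/10))`` — B reads are base errors;
    ``P(D|G_AB) = Binom(r_b; r_t, 1/2)``;
    ``P(D|U) = 10^(-min(qm_a, qm_b)/10)`` — the mapping error probability.

    A site with no reads is uninformative: both binomial terms are 1 by the
    ``pmf(0, 0, p) = 1`` convention.
    """
    err = 10.0 ** (-site.qb_b / 10.0)
    if site.r_t == 0:
        p_aa = p_ab = 1.0
    else:
        p_aa = float(np.exp(binom.logpmf(site.r_b, site.r_t, err)))
        p_ab = float(np.exp(binom.logpmf(site.r_b, site.r_t, 0.5)))
    p_u = 10.0 ** (-min(site.qm_a, site.qm_b) / 10.0)
    return p_aa, p_ab, p_u


def unreliable_posterior(site: SiteCounts, f_a: float, f_b: float,
                         pi_u: float) -> float:
    """Posterior probability that the position is unreliable in one control.

    Genotype priors come from Hardy-Weinberg: ``pi_AA = F_A**2`` and
    ``pi_AB = 2 F_A F_B``; the unreliable prior ``pi_U`` is a constant.
    """
    if f_a + f_b > 1.0 + 1e-9:
        raise ValueError(f"F_A + F_B must be <= 1, got {f_a} + {f_b}")
    p_aa, p_ab, p_u = control_state_likelihoods(site)
    pi_aa = f_a ** 2
    pi_ab = 2.0 * f_a * f_b
    denom = p_aa * pi_aa + p_ab * pi_ab + p_u * pi_u
    if denom == 0.0:
        raise ValueError(
            f"degenerate site {site.chrom}:{site.pos}: all state likelihoods are zero"
        )
    return p_u * pi_u / denom


def phred(prob: float, cap: float = PHRED_CAP) -> float:
    """Phred transform ``-10 log10(p)``, floored at 0 and capped."""
    if prob <= 0.0:
        return cap
    return float(np.clip(-10.0 * np.log10(prob), 0.0, cap))


@dataclass
class PanelStats:
    """Per-position reliability scores and per-exon control depths.

    ``positions`` columns: chrom, pos, mean_unreliable, phred, n_obs, flagged.
    ``exons`` columns: chrom, start, end, one depth column per control, and
    ``control_mean``.
    """

    positions: pd.DataFrame
    exons: pd.DataFrame
    n_controls: int
    pi_u: float

    def phred_score(self, chrom: str, pos: int) -> float:
        try:
            return float(self.positions.loc[(chrom, pos), "phred"])
        except KeyError:
            return 0.0

    def mean_unreliable(self, chrom: str, pos: int) -> float:
        try:
            return float(self.positions.loc[(chrom, pos), "mean_unreliable"])
        except KeyError:
            return 1.0

    def save(self, path: str) -> None:
        """Persist as a single versioned plain-text TSV bundle."""
        with open(path, "w") as fh:
            fh.write(f"#LUMOSCALL_PANEL\tv{PANEL_FORMAT_VERSION}\t"
                     f"n_controls={self.n_controls}\tpi_u={self.pi_u}\n")
            fh.write("#POSITIONS\n")
            self.positions.reset_index().to_csv(fh, sep="\t", index=False)
            fh.write("#EXONS\n")
            self.exons.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path: str) -> "PanelStats":
        with open(path) as fh:
            text = fh.read()
        header, _, rest = text.partition("\n")
        fields = header.split("\t")
        if not fields or fields[0] != "#LUMOSCALL_PANEL":
            raise ValueError(f"{path} is not a lumoscall panel file")
        meta = dict(f.split("=", 1) for f in fields[2:])
        pos_text, _, exon_text = rest.partition("#EXONS\n")
        pos_text = pos_text.replace("#POSITIONS\n", "", 1)
        positions = pd.read_csv(io.StringIO(pos_text), sep="\t", dtype={"chrom": str})
        positions = positions.set_index(["chrom", "pos"])
        exons = pd.read_csv(io.StringIO(exon_text), sep="\t", dtype={"chrom": str})
        return cls(positions=positions, exons=exons,
                   n_controls=int(meta["n_controls"]), pi_u=float(meta["pi_u"]))


def build_panel(
    control_sites: list[list[SiteCounts]],
    exon_depths: pd.DataFrame,
    priors: pd.DataFrame | None = None,
    pi_u: float = 0.05,
    f_p: float = 7.14e-5,
    phred_cap: float = PHRED_CAP,
) -> PanelStats:
    """Build panel statistics from >= 2 unmatched control samples.

    ``exon_depths`` must carry chrom/start/end plus one depth column per
    control. Population frequencies for the Hardy-Weinberg genotype priors
    are looked up in ``priors`` (F_A taken as 1 - F_B); alleles absent from
    the table get the unseen-allele frequency ``f_p``. Positions covered by
    no control are assigned the floor score and flagged.
    """
    if len(control_sites) < 2:
        raise ValueError("build_panel requires at least 2 control samples")

    freq: dict[tuple[str, int], float] = {}
    if priors is not None:
        for row in priors.itertuples(index=False):
            freq[(str(row.chrom), int(row.pos))] = float(row.f_b)

    acc: dict[tuple[str, int], list[float]] = {}
    for sample in control_sites:
        for site in sample:
            f_b = freq.get((site.chrom, site.pos), f_p)
            f_a = 1.0 - f_b
            post = unreliable_posterior(site, f_a, f_b, pi_u)
            acc.setdefault((site.chrom, site.pos), []).append(post)

    all_keys = sorted(acc, key=lambda k: (k[0], k[1]))
    rows = []
    for key in all_keys:
        posts = acc[key]
        mean_u = float(np.mean(posts))
        rows.append((key[0], key[1], mean_u, phred(mean_u, phred_cap), len(posts), False))
    positions = pd.DataFrame(
        rows, columns=["chrom", "pos", "mean_unreliable", "phred", "n_obs", "flagged"]
    ).set_index(["chrom", "pos"])

    depth_cols = [c for c in exon_depths.columns if c not in ("chrom", "start", "end")]
    if not depth_cols:
        raise ValueError("exon_depths must have at least one control depth column")
    exons = exon_depths.copy()
    exons["control_mean"] = exons[depth_cols].mean(axis=1)
    return PanelStats(positions=positions, exons=exons,
                      n_controls=len(control_sites), pi_u=pi_u)


def panel_scores_for_sites(panel: PanelStats, sites: list[SiteCounts],
                           phred_cap: float = PHRED_CAP) -> pd.DataFrame:
    """Panel phred / mean-unreliable for tumor sites; uncovered positions get
    the worst (floor) score and are flagged."""
    rows = []
    for s in sites:
        key = (s.chrom, s.pos)
        if key in panel.positions.index:
            rec = panel.positions.loc[key]
            rows.append((s.chrom, s.pos, float(rec["mean_unreliable"]),
                         float(rec["phred"]), False))
        else:
            logger.warning("position %s:%d absent from all controls", s.chrom, s.pos)
            rows.append((s.chrom, s.pos, 1.0, 0.0, True))
    return pd.DataFrame(rows, columns=["chrom", "pos", "mean_unreliable", "phred", "flagged"])
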