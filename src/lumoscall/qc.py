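"""Tumor site quality metrics and two-tier quadratic-discriminant filtering.

Step two of the caller. Sixteen site-level quality metrics are computed per
candidate position. Conservative per-metric thresholds seed a PASS training
group (a site must satisfy *all* PASS cutoffs) and a REJECT group (meeting
*any* REJECT cutoff suffices; REJECT wins on conflict). A quadratic
discriminant model is then fit per variant class (SNV and indel separately)
and used to score every site, labeled or not.

Two posteriors are emitted per site:

* ``PT`` — the strict PASS posterior from a QDA fit on PASS vs REJECT;
* ``PV`` — a lenient "real variant vs artifact" posterior from a QDA fit on
  everything-but-REJECT vs REJECT.

Sites tier as high quality (PT > T_PASS, eligible for calling), low quality
(only PV > T_PASS; reported but excluded from model fitting), or artifact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.stats import binomtest

from .formats_io import SiteCounts

logger = logging.getLogger("lumoscall")

METRIC_NAMES = [
    "panel_phred",        # panel reliability Phred score
    "log_depth",          # log10(total depth + 1)
    "baf",                # B-allele fraction
    "qb_a",               # mean base quality, A-supporting bases
    "qb_b",               # mean base quality, B-supporting bases
    "qm_a",               # mean mapping quality, A-supporting reads
    "qm_b",               # mean mapping quality, B-supporting reads
    "strand_bias",        # -log10 p of a two-sided fwd/rev balance test on B reads
    "b_fwd_frac",         # fraction of B reads on the forward strand
    "other_frac",         # reads supporting neither allele / total (clip proxy)
    "indel_len",          # |len(alt) - len(ref)|, 0 for SNVs
    "qm_diff",            # qm_a - qm_b
    "qb_diff",            # qb_a - qb_b
    "low_mapq_frac",      # mapping-error probability 10^(-min(qm)/10)
    "panel_unreliable",   # panel mean unreliable-posterior
    "homopolymer",        # indel allele is a homopolymer run
]

PASS, REJECT, UNLABELED = "PASS", "REJECT", "UNLABELED"


def strand_bias_score(fwd: int, rev: int) -> float:
    """-log10 p-value of a two-sided exact binomial balance test.

    Symmetric counts score ~0; fully one-sided counts score high.
    """
    n = fwd + rev
    if n == 0:
        return 0.0
    p = binomtest(fwd, n, 0.5).pvalue
    return float(-math.log10(max(p, 1e-300)))


def _is_homopolymer(seq: str) -> bool:
    return len(seq) > 1 and len(set(seq)) == 1


def compute_metrics(site: SiteCounts, panel_phred: float,
                    panel_unreliable: float) -> np.ndarray:
    """Deterministic, NaN-free 16-metric vector for one site."""
    baf = site.r_b / site.r_t if site.r_t > 0 else 0.0
    n_b = site.strand_b_fwd + site.strand_b_rev
    vec = np.array([
        panel_phred,
        math.log10(site.r_t + 1.0),
        baf,
        site.qb_a,
        site.qb_b,
        site.qm_a,
        site.qm_b,
        strand_bias_score(site.strand_b_fwd, site.strand_b_rev),
        site.strand_b_fwd / n_b if n_b > 0 else 0.5,
        (site.r_t - site.r_a - site.r_b) / site.r_t if site.r_t > 0 else 0.0,
        float(abs(len(site.b_allele) - len(site.ref_allele))),
        site.qm_a - site.qm_b,
        site.qb_a - site.qb_b,
        10.0 ** (-min(site.qm_a, site.qm_b) / 10.0),
        panel_unreliable,
        float(site.is_indel and (_is_homopolymer(site.b_allele)
                                 or _is_homopolymer(site.ref_allele))),
    ], dtype=float)
    assert vec.shape == (len(METRIC_NAMES),)
    return np.nan_to_num(vec, nan=0.0, posinf=0.0, neginf=0.0)


def metrics_table(sites: list[SiteCounts], panel_scores: pd.DataFrame) -> pd.DataFrame:
    """Metric vectors for a list of sites, aligned with panel scores."""
    assert len(sites) == len(panel_scores)
    rows = [
        compute_metrics(s, float(p.phred), float(p.mean_unreliable))
        for s, p in zip(sites, panel_scores.itertuples(index=False))
    ]
    return pd.DataFrame(rows, columns=METRIC_NAMES)


_OPS = {
    ">=": np.greater_equal, ">": np.greater,
    "<=": np.less_equal, "<": np.less,
}


def label_training_sites(metrics: pd.DataFrame,
                         pass_thresholds: dict[str, tuple[str, float]],
                         reject_thresholds: dict[str, tuple[str, float]]) -> np.ndarray:
    """Assign PASS / REJECT / UNLABELED training labels.

    PASS requires *all* PASS cutoffs to hold; REJECT requires *any* REJECT
    cutoff; a site meeting both is REJECT (conservative).
    """
    n = len(metrics)
    ok = np.ones(n, dtype=bool)
    for name, (op, value) in pass_thresholds.items():
        ok &= _OPS[op](metrics[name].to_numpy(), value)
    bad = np.zeros(n, dtype=bool)
    for name, (op, value) in reject_thresholds.items():
        bad |= _OPS[op](metrics[name].to_numpy(), value)
    labels = np.full(n, UNLABELED, dtype=object)
    labels[ok] = PASS
    labels[bad] = REJECT
    return labels


@dataclass
class QualityModel:
    """Quadratic discriminant model: per-class Gaussian with full covariance."""

    classes: list[str]
    means: list[np.ndarray]
    covs: list[np.ndarray]
    log_priors: list[float]
    _chol: list[np.ndarray] = field(default_factory=list, repr=False)

    @classmethod
    def fit(cls, X: np.ndarray, labels: np.ndarray,
            classes: list[str] | None = None,
            ridge_scale: float = 1e-6) -> "QualityModel":
        """Fit per-class mean/covariance; near-singular covariances are
        ridge-regularized with ``lambda = ridge_scale * trace / d`` and a
        warning."""
        if classes is None:
            classes = sorted(set(labels))
        d = X.shape[1]
        means, covs, log_priors, chols = [], [], [], []
        n_total = sum(int(np.sum(labels == c)) for c in classes)
        for c in classes:
            Xc = X[labels == c]
            if len(Xc) == 0:
                raise ValueError(f"no training samples for class {c!r}; relax thresholds")
            if len(Xc) < d + 1:
                logger.warning(
                    "class %s has %d samples for %d metrics; covariance will be "
                    "ridge-regularized", c, len(Xc), d)
            mu = Xc.mean(axis=0)
            cov = np.cov(Xc, rowvar=False, bias=False) if len(Xc) > 1 else np.zeros((d, d))
            cov = np.atleast_2d(cov)
            lam = ridge_scale * max(np.trace(cov), 1.0) / d
            cov = cov + lam * np.eye(d)
            while True:
                try:
                    chol = np.linalg.cholesky(cov)
                    break
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    logger.warning("singular covariance for class %s; ridge -> %.3g", c, lam)
                    cov = cov + lam * np.eye(d)
            means.append(mu)
            covs.append(cov)
            chols.append(chol)
            log_priors.append(math.log(len(Xc) / n_total))
        return cls(classes=classes, means=means, covs=covs,
                   log_priors=log_priors, _chol=chols)

    def _log_likelihood(self, X: np.ndarray) -> np.ndarray:
        """(n, n_classes) Gaussian log-densities."""
        X = np.atleast_2d(X)
        out = np.empty((X.shape[0], len(self.classes)))
        d = X.shape[1]
        for k, (mu, chol) in enumerate(zip(self.means, self._chol)):
            z = solve_triangular(chol, (X - mu).T, lower=True)
            maha = np.sum(z ** 2, axis=0)
            log_det = 2.0 * np.sum(np.log(np.diag(chol)))
            out[:, k] = -0.5 * (maha + log_det + d * math.log(2.0 * math.pi))
        return out

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """(n, n_classes) class posteriors; rows sum to 1."""
        ll = self._log_likelihood(X) + np.asarray(self.log_priors)
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        return p / p.sum(axis=1, keepdims=True)


def fit_quality_model(metrics: pd.DataFrame, labels: np.ndarray,
                      kind: str = "SNV") -> QualityModel:
    """Fit the strict PASS-vs-REJECT QDA for one variant class."""
    keep = np.isin(labels, [PASS, REJECT])
    model = QualityModel.fit(metrics.to_numpy()[keep], labels[keep],
                             classes=[PASS, REJECT])
    post = model.posterior(metrics.to_numpy()[keep])
    acc = float(np.mean((post[:, 0] > 0.5) == (labels[keep] == PASS)))
    logger.info("%s quality model training accuracy: %.4f (n=%d)", kind, acc,
                int(keep.sum()))
    return model


def fit_variant_model(metrics: pd.DataFrame, labels: np.ndarray,
                      kind: str = "SNV") -> QualityModel:
    """Fit the lenient variant-vs-artifact QDA: REJECT against everything else."""
    lenient = np.where(labels == REJECT, REJECT, "VARIANT").astype(object)
    return QualityModel.fit(metrics.to_numpy(), lenient, classes=["VARIANT", REJECT])


def score_sites(strict: QualityModel, lenient: QualityModel,
                metrics: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (PT, PV): strict PASS posterior and lenient variant posterior."""
    X = metrics.to_numpy()
    pt = strict.posterior(X)[:, 0]
    pv = lenient.posterior(X)[:, 0]
    return pt, pv


def quality_tiers(pt: np.ndarray, pv: np.ndarray, t_pass: float = 0.99) -> np.ndarray:
    """Tier per site: 'high' (PT > T), 'low' (PV > T only), else 'artifact'."""
    tiers = np.full(len(pt), "artifact", dtype=object)
    tiers[pv > t_pass] = "low"
    tiers[pt > t_pass] = "high"
    return tiers


def run_qc(sites: list[SiteCounts], panel_scores: pd.DataFrame,
           pass_thresholds: dict, reject_thresholds: dict,
           t_pass: float = 0.99) -> pd.DataFrame:
    """Full QC pass: metrics -> labels -> per-class QDA fits -> PT/PV tiers.

    SNVs and indels get separate models; if one class has no labeled indels
    (common for small panels) the SNV model scores them with a warning.
    """
    metrics = metrics_table(sites, panel_scores)
    labels = label_training_sites(metrics, pass_thresholds, reject_thresholds)
    is_indel = np.array([s.is_indel for s in sites], dtype=bool)

    pt = np.zeros(len(sites))
    pv = np.zeros(len(sites))
    groups = [("SNV", ~is_indel), ("indel", is_indel)]
    fitted: dict[str, tuple[QualityModel, QualityModel]] = {}
    for kind, mask in groups:
        if not mask.any():
            continue
        sub_metrics = metrics[mask]
        sub_labels = labels[mask]
        try:
            strict = fit_quality_model(sub_metrics, sub_labels, kind)
            lenient = fit_variant_model(sub_metrics, sub_labels, kind)
            fitted[kind] = (strict, lenient)
        except ValueError:
            if kind == "indel" and "SNV" in fitted:
                logger.warning("too few labeled indels; scoring indels with the SNV model")
                fitted[kind] = fitted["SNV"]
            else:
                raise
        pt[mask], pv[mask] = score_sites(*fitted[kind], sub_metrics)

    out = metrics.copy()
    out["label"] = labels
    out["pt"] = pt
    out["pv"] = pv
    out["tier"] = quality_tiers(pt, pv, t_pass)
    return out
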