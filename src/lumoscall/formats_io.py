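"""Input/output formats, domain records, and configuration defaults.

The caller consumes plain tab-separated tables rather than BAMs so that the
statistical model is decoupled from alignment:

* a *counts table* with one row per candidate site per sample (pileup
  summaries: read counts, mean base/mapping qualities, per-strand counts),
* a *priors table* mapping (chrom, pos, allele) to a population allele
  frequency and a cancer-database mutation count,
* per-exon mean read depths over a target BED,
* a YAML configuration holding the model parameters.

Calls are emitted as VCF 4.2 (via pysam) and copy-number segments as a
BED-like TSV.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

logger = logging.getLogger("lumoscall")

COUNTS_COLUMNS = [
    "chrom", "pos", "ref", "alt", "r_total", "r_ref", "r_alt",
    "qb_ref", "qb_alt", "qm_ref", "qm_alt", "alt_fwd", "alt_rev", "is_indel",
]

PRIORS_COLUMNS = ["chrom", "pos", "allele", "f_b", "omega", "known_germline"]


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteCounts:
    """Allele read counts and quality summaries for one site in one sample.

    ``r_a``/``r_b`` are the reads supporting the reference (A) and candidate
    (B) allele; ``qb_*``/``qm_*`` are mean base and mapping qualities in
    Phred units. Coordinates are 1-based.
    """

    chrom: str
    pos: int
    ref_allele: str
    b_allele: str
    r_t: int
    r_a: int
    r_b: int
    qb_a: float
    qb_b: float
    qm_a: float
    qm_b: float
    strand_b_fwd: int = 0
    strand_b_rev: int = 0
    is_indel: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("r_t", "r_a", "r_b", "strand_b_fwd", "strand_b_rev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.r_a + self.r_b > self.r_t:
            raise ValueError(
                f"r_a + r_b ({self.r_a + self.r_b}) exceeds r_t ({self.r_t}) "
                f"at {self.chrom}:{self.pos}"
            )
        for name in ("qb_a", "qb_b", "qm_a", "qm_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative (Phred units)")

    @property
    def baf(self) -> float:
        """B-allele fraction ``r_b / r_t`` (0 when the site has no reads)."""
        return self.r_b / self.r_t if self.r_t > 0 else 0.0


@dataclass(frozen=True)
class PriorsRecord:
    """Population frequency and cancer-count priors for one allele."""

    chrom: str
    pos: int
    allele: str
    f_b: float
    omega: int
    known_germline: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_b <= 1.0:
            raise ValueError(f"f_b must be in [0, 1], got {self.f_b}")
        if self.omega < 0 or int(self.omega) != self.omega:
            raise ValueError(f"omega must be a non-negative integer, got {self.omega}")


@dataclass(frozen=True)
class ExonDepth:
    """Mean read depth over one target exon (0-based half-open span)."""

    chrom: str
    start: int
    end: int
    tumor_depth: float = 0.0
    control_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start ({self.chrom}:{self.start}-{self.end})")
        if self.tumor_depth < 0 or self.control_depth < 0:
            raise ValueError("depths must be non-negative")


_DEFAULT_PASS_THRESHOLDS = {
    "qm_b": (">=", 50.0),
    "qm_a": (">=", 50.0),
    "qb_b": (">=", 28.0),
    "strand_bias": ("<=", 2.0),
    "panel_phred": (">=", 30.0),
}

_DEFAULT_REJECT_THRESHOLDS = {
    "qm_b": ("<", 20.0),
    "qb_b": ("<", 15.0),
    "panel_phred": ("<", 10.0),
    "strand_bias": (">", 8.0),
}


@dataclass
class Config:
    """Model parameters; defaults are the caller's standard operating point.

    The copy-number prior vector is over total copies N = 0, 1, 2, 3, >=4 and
    the minor-allele prior over M = 0, 1, >=2; both must sum to one.
    """

    K: int = 3
    f_pi: float = 0.5
    alpha_pi: float = 1.5
    cn_priors: list[float] = field(default_factory=lambda: [0.1, 0.15, 0.5, 0.15, 0.1])
    m_priors: list[float] = field(default_factory=lambda: [0.25, 0.5, 0.25])
    alpha_seg: float = 1e-5
    rho_SNV: float = 1e-5
    rho_indel: float = 1e-6
    F_p_SNV: float = 7.14e-5
    F_p_indel: float = 1.43e-5
    F_max_somatic: float = 1e-3
    Qm_min: float = 10.0
    Qb_min: float = 5.0
    T_PASS: float = 0.99
    T_somatic: float = 0.8
    T_germline: float = 0.8
    pi_U: float = 0.05
    em_tol: float = 1e-6
    max_outer_iters: int = 10
    rng_seed: int = 0
    # numerical / implementation knobs
    phred_cap: float = 250.0
    min_seg_width: int = 5
    unfolded_somatic_bb: bool = False
    shared_W: bool = True
    max_em_iters: int = 30
    pass_thresholds: dict = field(default_factory=lambda: dict(_DEFAULT_PASS_THRESHOLDS))
    reject_thresholds: dict = field(default_factory=lambda: dict(_DEFAULT_REJECT_THRESHOLDS))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        for name, vec, n in (("cn_priors", self.cn_priors, 5), ("m_priors", self.m_priors, 3)):
            if len(vec) != n:
                raise ValueError(f"{name} must have {n} entries")
            if abs(sum(vec) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1, got {sum(vec)!r}")
            if any(p < 0 for p in vec):
                raise ValueError(f"{name} entries must be non-negative")
        for name in ("T_PASS", "T_somatic", "T_germline", "pi_U", "f_pi",
                     "F_max_somatic", "F_p_SNV", "F_p_indel"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.alpha_pi <= 1.0:
            raise ValueError("alpha_pi must be > 1 for the f prior to have a mode")


def load_config(path: str | None = None) -> Config:
    """Load a :class:`Config` from YAML; absent file/keys fall back to defaults.

    Unknown keys raise ``ValueError`` listing the valid names.
    """
    overrides: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded:
            overrides = dict(loaded)
    valid = {f.name for f in dataclasses.fields(Config)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys are {sorted(valid)}"
        )
    return Config(**overrides)


# ---------------------------------------------------------------------------
# Counts tables
# ---------------------------------------------------------------------------

def load_counts(path: str) -> list[SiteCounts]:
    """Read a per-site counts table (TSV with the documented header).

    Rows violating the count invariants raise ``ValueError`` naming the
    offending line. An empty file yields an empty list with a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        logger.warning("counts file %s is empty", path)
        return []
    if df.empty:
        logger.warning("counts file %s has no data rows", path)
        return []
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    sites = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            sites.append(
                SiteCounts(
                    chrom=str(row.chrom), pos=int(row.pos),
                    ref_allele=str(row.ref), b_allele=str(row.alt),
                    r_t=int(row.r_total), r_a=int(row.r_ref), r_b=int(row.r_alt),
                    qb_a=float(row.qb_ref), qb_b=float(row.qb_alt),
                    qm_a=float(row.qm_ref), qm_b=float(row.qm_alt),
                    strand_b_fwd=int(row.alt_fwd), strand_b_rev=int(row.alt_rev),
                    is_indel=bool(row.is_indel),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {idx}: {exc}") from exc
    return sites


def write_counts(sites: Iterable[SiteCounts], path: str) -> None:
    """Write sites to a counts TSV (inverse of :func:`load_counts`)."""
    rows = [
        (s.chrom, s.pos, s.ref_allele, s.b_allele, s.r_t, s.r_a, s.r_b,
         s.qb_a, s.qb_b, s.qm_a, s.qm_b, s.strand_b_fwd, s.strand_b_rev,
         int(s.is_indel))
        for s in sites
    ]
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, sep="\t", index=False)


def load_priors(path: str) -> pd.DataFrame:
    """Read the priors table (chrom, pos, allele, f_b, omega, known_germline)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = set(PRIORS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing priors columns {sorted(missing)}")
    if ((df["f_b"] < 0) | (df["f_b"] > 1)).any():
        raise ValueError(f"{path}: f_b outside [0, 1]")
    if (df["omega"] < 0).any():
        raise ValueError(f"{path}: negative omega")
    return df


def write_priors(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, columns=PRIORS_COLUMNS)


def load_bed(path: str) -> list[tuple[str, int, int]]:
    """Read a 3+ column BED (0-based half-open) of target exons."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path} line {ln}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path} line {ln}: end <= start")
            out.append((chrom, start, end))
    return out


def load_exon_depths(path: str) -> pd.DataFrame:
    """Read a per-exon depth table: chrom, start, end, then one depth column
    per sample."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return df


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_INFO_FIELDS = [
    ("P_SOMATIC", "1", "Float", "Posterior probability the variant is somatic"),
    ("P_GERMLINE_HET", "1", "Float", "Posterior probability of germline heterozygous"),
    ("P_HOM", "1", "Float", "Posterior probability of germline homozygous reference"),
    ("P_OTHER", "1", "Float", "Posterior probability of the 'other' model"),
    ("CLONE", "1", "Integer", "Index (1-based) of the most likely clone"),
    ("EXP_AF", "1", "Float", "Expected somatic allele fraction for the assigned clone"),
    ("CN", "1", "Integer", "Total copy number of the enclosing segment"),
    ("MINOR_CN", "1", "Integer", "Minor allele copy number of the enclosing segment"),
    ("PT", "1", "Float", "Posterior probability of the strict PASS quality tier"),
    ("PV", "1", "Float", "Posterior probability the site is a real variant, not artifact"),
    ("KNOWN_GERMLINE", "0", "Flag", "Allele is a known germline database entry"),
]

_LABEL_TO_FILTER = {
    "SOMATIC": "PASS",
    "GERMLINE_HET": "PASS",
    "GERMLINE_HOM": "PASS",
    "OTHER": "LowQual",
    "UNCALLED": "LowQual",
}


def _chrom_sort_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def write_calls_vcf(calls: Sequence, path: str) -> None:
    """Write classified calls as VCF 4.2.

    FILTER is PASS for called sites in the high-quality tier, LowQual for
    sites with PT < T_PASS but PV > T_PASS (reported, not trusted), and
    REJECT for artifact-tier sites. Records must be coordinate-sorted.
    """
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    header.add_line('##source=lumoscall')
    for name, number, vtype, desc in _INFO_FIELDS:
        header.add_meta("INFO", items=[("ID", name), ("Number", number),
                                       ("Type", vtype), ("Description", desc)])
    header.add_meta("FILTER", items=[("ID", "LowQual"),
                                     ("Description", "PT below threshold but PV above")])
    header.add_meta("FILTER", items=[("ID", "REJECT"),
                                     ("Description", "Artifact tier: PV below threshold")])
    chroms = []
    for call in calls:
        if call.site.chrom not in chroms:
            chroms.append(call.site.chrom)
    for chrom in sorted(chroms, key=_chrom_sort_key):
        header.add_meta("contig", items=[("ID", chrom)])

    keys = [(_chrom_sort_key(c.site.chrom), c.site.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be coordinate-sorted before writing VCF")

    with pysam.VariantFile(path, "w", header=header) as out:
        for call in calls:
            s = call.site
            rec = out.new_record(
                contig=s.chrom, start=s.pos - 1, stop=s.pos - 1 + len(s.ref_allele),
                alleles=(s.ref_allele, s.b_allele), filter=call.filter_status,
            )
            rec.info["P_SOMATIC"] = round(call.p_somatic, 6)
            rec.info["P_GERMLINE_HET"] = round(call.p_germline_het, 6)
            rec.info["P_HOM"] = round(call.p_hom, 6)
            rec.info["P_OTHER"] = round(call.p_other, 6)
            rec.info["CLONE"] = int(call.clone)
            rec.info["EXP_AF"] = round(call.expected_af, 6)
            rec.info["CN"] = int(call.cn)
            rec.info["MINOR_CN"] = int(call.minor_cn)
            rec.info["PT"] = round(call.pt, 6)
            rec.info["PV"] = round(call.pv, 6)
            if getattr(call, "known_germline", False):
                rec.info["KNOWN_GERMLINE"] = True
            out.write(rec)


def read_calls_vcf(path: str) -> pd.DataFrame:
    """Read a lumoscall VCF back into a DataFrame (round-trip support)."""
    rows = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            rows.append({
                "chrom": rec.contig, "pos": rec.pos,
                "ref": rec.alleles[0], "alt": rec.alleles[1],
                "filter": list(rec.filter.keys())[0] if len(rec.filter) else "PASS",
                "p_somatic": info.get("P_SOMATIC", np.nan),
                "p_germline_het": info.get("P_GERMLINE_HET", np.nan),
                "p_hom": info.get("P_HOM", np.nan),
                "p_other": info.get("P_OTHER", np.nan),
                "clone": info.get("CLONE", 0),
                "expected_af": info.get("EXP_AF", np.nan),
                "cn": info.get("CN", -1),
                "minor_cn": info.get("MINOR_CN", -1),
                "pt": info.get("PT", np.nan),
                "pv": info.get("PV", np.nan),
                "known_germline": bool(info.get("KNOWN_GERMLINE", False)),
            })
    return pd.DataFrame(rows)


def write_segments(segments: Sequence, path: str) -> None:
    """Emit fitted segments as BED-like TSV:
    chrom, start, end, clone, f, N, M, n_exons, mean_ratio."""
    rows = [
        (seg.chrom, seg.start, seg.end, seg.clone, round(seg.f, 6),
         seg.n_total, seg.m_minor, seg.n_exons, round(seg.mean_ratio, 6))
        for seg in segments
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "clone", "f", "N", "M", "n_exons", "mean_ratio"],
    ).to_csv(path, sep="\t", index=False)
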