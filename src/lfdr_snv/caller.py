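"""Genome-wide LFDR variant calling: pre-filter, iterative fit, decide,
post-filter.

The calling procedure has three stages:

1. *Pre-processing* — sites failing minimum mean base-call quality (BQ) or
   mapping quality (MQ) are excluded; retained sites get their count split
   (K, R, M, X1, X2) and a quality-derived error rate e_i.

2. *Iterative empirical-Bayes fit* — starting from an initial null
   proportion pi0 (the fraction of sites with no alternative reads) and an
   initial allele-frequency atom set, the loop alternates: score every site
   (LFDR), tentatively call sites with psi <= tau, re-estimate pi0 as one
   minus the called fraction, and (except in "uniform" mode) rebuild the
   atom set from the empirical allele frequencies of the tentative calls.
   Iteration stops when pi0 moves by less than epsilon.

3. *Post-processing* — calls below the allele-frequency threshold (AFT) or
   depth threshold (DPT) are removed.

Three modes govern g(.): "empirical" initialises atoms from every site
with at least one dominant-alternative read; "uniform_empirical" starts
from N uniform draws on (0, 1) but updates empirically from the first
iteration on; "uniform" keeps the initial uniform draws fixed throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from lfdr_snv import counts_io
from lfdr_snv.counts_io import CallRecord, RawBaseRecord, SiteCounts
from lfdr_snv.error_model import (
    GLOBAL_ERROR_RATE,
    SiteQuality,
    allele_mean_quality,
    error_rate_from_quality,
)
from lfdr_snv.likelihood import (
    ModelParams,
    LfdrResult,
    lfdr_arrays,
    log_alt_likelihood_empirical_arrays,
    log_null_likelihood_arrays,
)

logger = logging.getLogger(__name__)

G_MODES = ("empirical", "uniform_empirical", "uniform")


@dataclass(frozen=True)
class CallerConfig:
    """Tunable parameters of the calling algorithm.

    tau is the LFDR call threshold; epsilon the convergence tolerance on
    pi0; n_uniform_atoms the number N of uniform(0,1) atoms in the uniform
    modes; min_bq/min_mq the pre-filter quality floors (Phred);
    aft/dpt the post-filter allele-frequency and depth floors;
    global_error_rate, when set, replaces quality-derived per-site error
    rates with a single constant (0.01 is the recommended value);
    pi0_init of None means "fraction of sites with M = 0";
    prefilter_af_depth applies AFT/DPT already at the pre-processing stage,
    which changes what the fitted pi0 refers to (the filtered rather than
    the original site universe) and is therefore off by default.
    """

    g_mode: str = "empirical"
    tau: float = 1e-20
    epsilon: float = 0.001
    n_uniform_atoms: int = 1000
    min_bq: float = 20.0
    min_mq: float = 30.0
    aft: float = 0.01
    dpt: int = 10
    max_iter: int = 100
    seed: int = 17
    pi0_init: float | None = None
    global_error_rate: float | None = None
    prefilter_af_depth: bool = False

    def __post_init__(self) -> None:
        if self.g_mode not in G_MODES:
            raise ValueError(f"g_mode must be one of {G_MODES}, got {self.g_mode!r}")
        if not (0.0 < self.tau <= 1.0):
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.min_bq < 0 or self.min_mq < 0 or self.aft < 0 or self.dpt < 0:
            raise ValueError("thresholds must be >= 0")
        if self.pi0_init is not None and not (0.0 <= self.pi0_init <= 1.0):
            raise ValueError("pi0_init must be in [0, 1]")


@dataclass
class CallSet:
    """Full output of one calling run: per-site scores, the called subset,
    and the fit trajectory for auditability."""

    sites: list[SiteCounts]
    qualities: list[SiteQuality]
    log10_psi: np.ndarray
    psi: np.ndarray
    delta: np.ndarray  # tentative decisions before post-filtering
    called_idx: np.ndarray  # indices of final calls (post-filtered)
    calls: list[CallRecord]
    pi0_hat: float
    atoms: np.ndarray
    pi0_trajectory: list[float]
    s_trajectory: list[int]
    n_iter: int
    converged: bool
    config: CallerConfig

    @property
    def params(self) -> ModelParams:
        return ModelParams(pi0=self.pi0_hat, theta_atoms=self.atoms)


def _site_quality(record: RawBaseRecord, counts: SiteCounts,
                  config: CallerConfig) -> SiteQuality:
    """Per-class and weighted site quality for one retained site."""
    class_base = {"R": counts.ref_base, "M": counts.alt_base}
    # X1/X2 bases: the two non-ref, non-dominant bases ordered by count desc
    others = sorted(
        (b for b in counts_io.BASES if b not in (counts.ref_base, counts.alt_base)),
        key=lambda b: (-record.counts[b], b),
    )
    class_base["X1"], class_base["X2"] = others[0], others[1]
    weights = {"R": counts.R, "M": counts.M, "X1": counts.X1, "X2": counts.X2}
    q_by_class = {
        lab: allele_mean_quality(record.mean_bq[class_base[lab]], record.mean_mq[class_base[lab]])
        for lab, w in weights.items() if w > 0
    }
    k = counts.K
    mean_bq = sum(record.mean_bq[class_base[lab]] * w for lab, w in weights.items()) / k
    mean_mq = sum(record.mean_mq[class_base[lab]] * w for lab, w in weights.items()) / k
    q = sum(q_by_class[lab] * w for lab, w in weights.items() if w > 0) / k
    if config.global_error_rate is not None:
        e = config.global_error_rate
    else:
        e = error_rate_from_quality(q)
    return SiteQuality(q_by_class=q_by_class, q=q, e=e, mean_bq=mean_bq, mean_mq=mean_mq)


def prefilter_sites(records: list[RawBaseRecord], config: CallerConfig
                    ) -> tuple[list[SiteCounts], list[SiteQuality]]:
    """Quality pre-filter: drop K=0 sites and sites whose count-weighted
    mean BQ or mean MQ falls below the configured floors; compute counts and
    error rates for the survivors."""
    sites: list[SiteCounts] = []
    quals: list[SiteQuality] = []
    n_dropped = 0
    for rec in records:
        counts = counts_io.select_alleles(rec)
        if counts.K == 0:
            n_dropped += 1
            continue
        sq = _site_quality(rec, counts, config)
        if sq.mean_bq < config.min_bq or sq.mean_mq < config.min_mq:
            n_dropped += 1
            continue
        if config.prefilter_af_depth and (counts.af < config.aft or counts.K < config.dpt):
            n_dropped += 1
            continue
        sites.append(counts)
        quals.append(sq)
    if n_dropped:
        logger.info("pre-filter dropped %d of %d sites", n_dropped, len(records))
    return sites, quals


def initialize_atoms(sites: list[SiteCounts], config: CallerConfig) -> np.ndarray:
    """Initial allele-frequency atom set for the configured g mode.

    empirical: the AFs M/K of every site with M > 0.  uniform and
    uniform_empirical: N seeded uniform(0, 1] draws.
    """
    if config.g_mode == "empirical":
        atoms = np.array([s.af for s in sites if s.M > 0])
        if atoms.size == 0:
            raise ValueError(
                "empirical g-mode needs at least one site with alternative reads; "
                "use uniform or uniform_empirical mode"
            )
        return atoms
    rng = np.random.default_rng(config.seed)
    return 1.0 - rng.random(config.n_uniform_atoms)


def _arrays(sites: list[SiteCounts]) -> dict[str, np.ndarray]:
    return {
        "K": np.array([s.K for s in sites], float),
        "R": np.array([s.R for s in sites], float),
        "M": np.array([s.M for s in sites], float),
        "X1": np.array([s.X1 for s in sites], float),
        "X2": np.array([s.X2 for s in sites], float),
    }


def lfdr_pass(sites: list[SiteCounts], e, params: ModelParams
              ) -> tuple[np.ndarray, np.ndarray]:
    """Score every site: returns (log10_psi, psi) arrays.

    ``e`` is a scalar or per-site array of error probabilities.
    Deterministic given its inputs; each site uses its own e_i.
    """
    arr = _arrays(sites)
    e = np.broadcast_to(np.asarray(e, float), arr["K"].shape)
    log_p0 = log_null_likelihood_arrays(arr["K"], arr["R"], arr["M"], arr["X1"], arr["X2"], e)
    log_p1 = log_alt_likelihood_empirical_arrays(
        arr["K"], arr["R"], arr["M"], arr["X1"], arr["X2"], e, params.theta_atoms
    )
    log10_psi = lfdr_arrays(log_p0, log_p1, params.pi0)
    with np.errstate(over="ignore"):
        psi = np.power(10.0, np.minimum(log10_psi, 0.0))
    return log10_psi, psi


def postfilter_calls(callset: CallSet, config: CallerConfig | None = None) -> CallSet:
    """Apply the AF and depth post-filters (M/K >= AFT, K >= DPT) to the
    called subset, returning an updated CallSet."""
    config = config or callset.config
    keep = [
        i for i in callset.called_idx
        if callset.sites[i].af >= config.aft and callset.sites[i].K >= config.dpt
    ]
    callset.called_idx = np.array(keep, dtype=int)
    callset.calls = [_call_record(callset, i) for i in keep]
    return callset


def _call_record(callset: CallSet, i: int) -> CallRecord:
    s = callset.sites[i]
    return CallRecord(
        chrom=s.chrom, pos=s.pos, ref=s.ref_base, alt=s.alt_base or ".",
        K=s.K, R=s.R, M=s.M,
        psi=float(callset.psi[i]), log10_psi=float(callset.log10_psi[i]),
    )


def run_algorithm1(records: list[RawBaseRecord], config: CallerConfig | None = None) -> CallSet:
    """The full iterative calling procedure on a raw count table.

    Each iteration j: (i) LFDR pass with the current (pi0, atoms);
    (ii) tentative calls = {i : psi_i <= tau}; (iii) pi0 <- 1 - called
    fraction; (iv) unless g_mode == "uniform", atoms <- empirical AFs of the
    tentative calls with M > 0 (kept unchanged if that set is empty).  Stops
    when |pi0_j - pi0_{j-1}| < epsilon or at max_iter; non-convergence is
    flagged but results are still returned.  Post-filters are applied to the
    final tentative calls.
    """
    config = config or CallerConfig()
    sites, quals = prefilter_sites(records, config)
    if not sites:
        raise ValueError("no sites retained after pre-filtering")
    p = len(sites)
    e = np.array([q.e for q in quals])
    m_arr = np.array([s.M for s in sites])
    af_arr = np.array([s.af for s in sites])

    pi0 = config.pi0_init if config.pi0_init is not None else float(np.mean(m_arr == 0))
    any_alt = bool(np.any(m_arr > 0))
    if config.g_mode == "empirical" and not any_alt:
        # Degenerate all-reference input: pi0 stays at 1 and no atom set can
        # be formed; score directly (psi = 1 everywhere at pi0 = 1).
        atoms = np.array([0.5])
    else:
        atoms = initialize_atoms(sites, config)

    log10_tau = math.log10(config.tau)
    pi0_traj = [pi0]
    s_traj: list[int] = []
    converged = False
    n_iter = 0
    log10_psi = np.zeros(p)
    psi = np.ones(p)
    tentative = np.zeros(p, dtype=bool)

    for j in range(1, config.max_iter + 1):
        n_iter = j
        s_traj.append(int(atoms.size))
        params = ModelParams(pi0=pi0, theta_atoms=atoms)
        log10_psi, psi = lfdr_pass(sites, e, params)
        with np.errstate(invalid="ignore"):
            tentative = log10_psi <= log10_tau
        tentative &= ~np.isnan(log10_psi)
        pi0_new = 1.0 - float(tentative.sum()) / p
        if config.g_mode != "uniform":
            sel = tentative & (m_arr > 0)
            if sel.any():
                atoms = af_arr[sel].copy()
            # an empty tentative-call set keeps the previous atoms
        delta_pi0 = abs(pi0_new - pi0)
        pi0 = pi0_new
        pi0_traj.append(pi0)
        logger.info("iteration %d: pi0=%.6f, s=%d, tentative calls=%d",
                    j, pi0, atoms.size, int(tentative.sum()))
        if delta_pi0 < config.epsilon:
            converged = True
            break
    if not converged:
        logger.warning("pi0 did not converge within %d iterations", config.max_iter)

    delta = tentative.astype(int)
    callset = CallSet(
        sites=sites, qualities=quals, log10_psi=log10_psi, psi=psi, delta=delta,
        called_idx=np.flatnonzero(tentative), calls=[],
        pi0_hat=pi0, atoms=atoms, pi0_trajectory=pi0_traj, s_trajectory=s_traj,
        n_iter=n_iter, converged=converged, config=config,
    )
    if not config.prefilter_af_depth:
        callset = postfilter_calls(callset, config)
    else:
        callset.calls = [_call_record(callset, i) for i in callset.called_idx]
    return callset


def callset_to_vcf(callset: CallSet, path: str | None = None) -> str:
    """Write the final calls as annotated VCF text (see counts_io)."""
    meta = {
        "pi0": f"{callset.pi0_hat:.6g}",
        "g_mode": callset.config.g_mode,
        "lfdr_threshold": f"{callset.config.tau:.6g}",
        "iterations": callset.n_iter,
        "converged": int(callset.converged),
        "atoms": callset.atoms.size,
    }
    return counts_io.write_calls_vcf(callset.calls, metadata=meta, path=path)
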