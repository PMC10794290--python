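"""Re-scoring and prioritization of another caller's variant list.

Given a count table over all assayed sites and the list of variants some
external caller reported, the prioritizer estimates pi0 as the fraction of
assayed sites the caller did NOT call, takes the empirical allele-frequency
distribution of the called sites as g(.), and performs a single LFDR pass
over the called sites — no iteration.  Calls are then ranked from most to
least probable variant (ascending LFDR) and can be thresholded, which can
only remove calls and therefore can never increase sensitivity against any
truth set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from lfdr_snv import counts_io
from lfdr_snv.caller import CallerConfig, _site_quality, prefilter_sites
from lfdr_snv.counts_io import CallRecord, ExternalCall, RawBaseRecord, SiteCounts
from lfdr_snv.likelihood import ModelParams
from lfdr_snv.caller import lfdr_pass

logger = logging.getLogger(__name__)


@dataclass
class RankedCall:
    """An external call with its matched counts, LFDR score and rank
    (1 = most probable variant)."""

    call: ExternalCall
    counts: SiteCounts
    psi: float
    log10_psi: float
    rank: int


def _recount_for_alt(record: RawBaseRecord, alt: str) -> SiteCounts:
    """Counts with the caller's ALT treated as the dominant allele.

    When the caller's ALT disagrees with the table's dominant alternative,
    the caller's ALT count becomes M and the remaining two non-reference
    counts become X1 >= X2.
    """
    ref = record.ref_base
    others = sorted(
        (record.counts[b] for b in counts_io.BASES if b not in (ref, alt)),
        reverse=True,
    )
    r, m = record.counts[ref], record.counts[alt]
    return SiteCounts(
        chrom=record.chrom, pos=record.pos, ref_base=ref, alt_base=alt,
        K=r + m + others[0] + others[1], R=r, M=m, X1=others[0], X2=others[1],
    )


def run_algorithm2(records: list[RawBaseRecord], calls: list[ExternalCall],
                   config: CallerConfig | None = None) -> list[RankedCall]:
    """Single-pass LFDR scoring of an external call list.

    pi0_hat = (p - n_called) / p over the p assayed (pre-filtered) sites;
    atoms = empirical AFs at called sites with M > 0.  Output is sorted
    ascending by log10 LFDR with ties broken by (chrom, pos).  Calls that
    match no assayed site are reported and skipped.
    """
    config = config or CallerConfig()
    sites, quals = prefilter_sites(records, config)
    if not sites:
        raise ValueError("no assayed sites retained after pre-filtering")
    by_pos = {(s.chrom, s.pos): i for i, s in enumerate(sites)}
    rec_by_pos = {(r.chrom, r.pos): r for r in records}

    matched: list[tuple[ExternalCall, SiteCounts, float]] = []
    n_unmatched = 0
    for call in calls:
        idx = by_pos.get((call.chrom, call.pos))
        if idx is None:
            n_unmatched += 1
            logger.warning("call %s:%d has no assayed count record; skipped", call.chrom, call.pos)
            continue
        counts = sites[idx]
        e = quals[idx].e
        if counts.alt_base != call.alt and counts.M > 0:
            logger.info(
                "caller ALT %s differs from dominant alternative %s at %s:%d; "
                "scoring with the caller's ALT count as M",
                call.alt, counts.alt_base, call.chrom, call.pos,
            )
        if counts.alt_base != call.alt:
            counts = _recount_for_alt(rec_by_pos[(call.chrom, call.pos)], call.alt)
        matched.append((call, counts, e))
    if n_unmatched:
        logger.info("%d external calls had no matching count record", n_unmatched)
    if not matched:
        raise ValueError("no external call matches an assayed site")

    p = len(sites)
    n_called = len(matched)
    pi0_hat = (p - n_called) / p
    atoms = np.array([c.af for _, c, _ in matched if c.M > 0])
    if atoms.size == 0:
        raise ValueError("no called site has alternative reads; cannot form g(.)")

    call_sites = [c for _, c, _ in matched]
    e_arr = np.array([e for _, _, e in matched])
    if pi0_hat == 0.0:
        # every assayed site was called: the null component has no mass
        log10_psi = np.full(n_called, -np.inf)
        psi = np.zeros(n_called)
    else:
        log10_psi, psi = lfdr_pass(call_sites, e_arr, ModelParams(pi0=pi0_hat, theta_atoms=atoms))

    order = sorted(
        range(n_called),
        key=lambda i: (log10_psi[i], matched[i][0].chrom, matched[i][0].pos),
    )
    ranked = [
        RankedCall(call=matched[i][0], counts=matched[i][1],
                   psi=float(psi[i]), log10_psi=float(log10_psi[i]), rank=r + 1)
        for r, i in enumerate(order)
    ]
    return ranked


def threshold_ranked(ranked: list[RankedCall], tau: float) -> list[RankedCall]:
    """Keep ranked calls with psi <= tau (log10-scale comparison, boundary
    inclusive).  A strict subset operation: never adds calls."""
    if tau >= 1.0:
        return list(ranked)
    log10_tau = np.log10(tau) if tau > 0 else -np.inf
    return [r for r in ranked if r.log10_psi <= log10_tau]


def ranked_to_vcf(ranked: list[RankedCall], metadata=None, path: str | None = None) -> str:
    """Serialize a ranked list as VCF with RANK and L10LFDR INFO keys."""
    records = [
        CallRecord(
            chrom=r.call.chrom, pos=r.call.pos, ref=r.call.ref, alt=r.call.alt,
            K=r.counts.K, R=r.counts.R, M=r.counts.M,
            psi=r.psi, log10_psi=r.log10_psi, rank=r.rank,
        )
        for r in ranked
    ]
    return counts_io.write_calls_vcf(records, metadata=metadata, path=path)
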