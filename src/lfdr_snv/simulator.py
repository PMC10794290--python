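"""Synthetic count tables with the caller's exact generative structure.

Each simulated site draws an allele frequency theta that is 0 with
probability pi0 (non-mutant) and otherwise comes from a configurable
mixture g(.) — by default bimodal, concentrated near 0.5 (heterozygous)
and 1.0 (homozygous), the shape germline allele frequencies take in real
panels.  Read counts are then multinomial over the four alleles with the
model's error-perturbed category probabilities, and the table is emitted in
bam-readcount dialect with Phred qualities chosen so the quality-derived
error model reproduces the generative error rate exactly.

The emitted qualities are uniform across allele classes (BQ = MQ = Q with
Q = -10 log10 e); an optional jitter perturbs per-class qualities for
robustness testing, in which case the recovered error rate is only
approximate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lfdr_snv.counts_io import BASES, RawBaseRecord, parse_readcount_table
from lfdr_snv.error_model import phred_from_error_rate


@dataclass(frozen=True)
class GSpec:
    """Mixture specification for the alternative allele frequency g(.).

    kinds:
      - "bimodal": equal-weight heterozygous component, truncated normal
        centred at ``het_mean`` (sd ``het_sd``) on (0, 1), and homozygous
        component 1 - |N(0, hom_sd)| hugging 1.0;
      - "point": a point mass at ``point``;
      - "uniform": uniform on (0, 1].
    """

    kind: str = "bimodal"
    het_mean: float = 0.5
    het_sd: float = 0.05
    hom_sd: float = 0.02
    het_weight: float = 0.5
    point: float = 0.5

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        if self.kind == "point":
            return np.full(n, self.point)
        if self.kind == "uniform":
            return 1.0 - rng.random(n)
        if self.kind == "bimodal":
            is_het = rng.random(n) < self.het_weight
            a = (0.0 - self.het_mean) / self.het_sd
            b = (1.0 - self.het_mean) / self.het_sd
            het = stats.truncnorm.rvs(a, b, loc=self.het_mean, scale=self.het_sd,
                                      size=n, random_state=rng)
            hom = 1.0 - np.abs(rng.normal(0.0, self.hom_sd, size=n))
            theta = np.where(is_het, het, hom)
            return np.clip(theta, 1e-6, 1.0)
        raise ValueError(f"unknown g kind {self.kind!r}")


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    depth_dist "fixed" gives every site K = depth; "poisson" draws
    K ~ Poisson(depth) (zero-depth sites are kept in the table and are the
    caller's job to drop).
    """

    p: int = 20000
    pi0_true: float = 0.95
    g_spec: GSpec = field(default_factory=GSpec)
    depth: int = 100
    depth_dist: str = "fixed"
    e_true: float = 0.01
    seed: int = 17
    chrom: str = "sim1"
    quality_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not (0.0 <= self.pi0_true <= 1.0):
            raise ValueError("pi0_true must be in [0, 1]")
        if not (0.0 <= self.e_true < 1.0):
            raise ValueError("e_true must be in [0, 1)")
        if self.depth_dist not in ("fixed", "poisson"):
            raise ValueError(f"unknown depth_dist {self.depth_dist!r}")


@dataclass
class SimulatedData:
    """Simulator output: raw per-base records, the truth table, and the
    count-table text they round-trip through."""

    records: list[RawBaseRecord]
    truth: pd.DataFrame  # chrom, pos, ref, alt, theta, is_mutant

    def to_readcount_text(self) -> str:
        lines = []
        for rec in self.records:
            blocks = [
                f"{b}:{rec.counts[b]}:{rec.mean_mq[b]:.2f}:{rec.mean_bq[b]:.2f}"
                for b in BASES
            ]
            lines.append(
                f"{rec.chrom}\t{rec.pos}\t{rec.ref_base}\t{rec.depth}\t" + "\t".join(blocks)
            )
        return "\n".join(lines) + "\n"


def sample_theta(spec: SimulationSpec, rng: np.random.Generator | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Draw the allele-frequency vector and truth labels.

    theta_i = 0 with probability pi0, else a draw from g; a site is labelled
    mutant iff theta_i > 0.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    is_mutant = rng.random(spec.p) < (1.0 - spec.pi0_true)
    theta = np.zeros(spec.p)
    n_mut = int(is_mutant.sum())
    theta[is_mutant] = spec.g_spec.sample(n_mut, rng)
    return theta, is_mutant


def simulate_dataset(spec: SimulationSpec) -> SimulatedData:
    """Generate a full synthetic dataset: counts + qualities + truth.

    Per site: a reference base is drawn uniformly; mutant sites get an
    alternative base drawn uniformly from the other three; reads follow
    Multinomial(K; p_R, p_M, e/3, e/3) with the model's category
    probabilities at (theta_i, e); the two e/3 categories land on the two
    remaining bases.  Qualities are emitted so that the error model recovers
    the generative e exactly (unless jitter is requested).
    """
    rng = np.random.default_rng(spec.seed)
    theta, is_mutant = sample_theta(spec, rng)
    p = spec.p
    ref_idx = rng.integers(0, 4, size=p)
    # alt base: uniform among the three non-reference bases (used for mutant
    # sites; for null sites the choice is immaterial as theta=0 symmetrises
    # the three error categories)
    alt_offset = rng.integers(1, 4, size=p)
    alt_idx = (ref_idx + alt_offset) % 4
    if spec.depth_dist == "fixed":
        depths = np.full(p, spec.depth)
    else:
        depths = rng.poisson(spec.depth, size=p)
    e = spec.e_true
    p_r = theta * e / 3.0 + (1.0 - theta) * (1.0 - e)
    p_m = theta * (1.0 - e) + (1.0 - theta) * e / 3.0
    probs = np.column_stack([p_r, p_m, np.full(p, e / 3.0), np.full(p, e / 3.0)])
    # e = 0 has no finite Phred representation; emit the conventional cap
    q = phred_from_error_rate(e) if e > 0 else 93.0

    records: list[RawBaseRecord] = []
    truth_rows = []
    for i in range(p):
        draw = rng.multinomial(depths[i], probs[i])
        ri, ai = int(ref_idx[i]), int(alt_idx[i])
        other = [j for j in range(4) if j not in (ri, ai)]
        counts = {b: 0 for b in BASES}
        counts[BASES[ri]] = int(draw[0])
        counts[BASES[ai]] = int(draw[1])
        counts[BASES[other[0]]] = int(draw[2])
        counts[BASES[other[1]]] = int(draw[3])
        if spec.quality_jitter > 0.0:
            quals = {b: max(0.0, q + rng.normal(0.0, spec.quality_jitter)) for b in BASES}
        else:
            quals = {b: q for b in BASES}
        records.append(
            RawBaseRecord(
                chrom=spec.chrom, pos=i + 1, ref_base=BASES[ri], depth=int(depths[i]),
                counts=counts,
                mean_mq={b: round(quals[b], 2) for b in BASES},
                mean_bq={b: round(quals[b], 2) for b in BASES},
            )
        )
        truth_rows.append(
            (spec.chrom, i + 1, BASES[ri], BASES[ai] if is_mutant[i] else ".",
             float(theta[i]), bool(is_mutant[i]))
        )
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos", "ref", "alt", "theta", "is_mutant"])
    return SimulatedData(records=records, truth=truth)


def write_truth_table(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def roundtrip_records(data: SimulatedData) -> list[RawBaseRecord]:
    """Parse the emitted text back into records (identity on counts)."""
    return parse_readcount_table(io.StringIO(data.to_readcount_text()))
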