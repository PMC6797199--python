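"""Horizontal transposon transfer detection by synonymous-divergence contrast.

Under vertical transmission a TE diverges between two host species for exactly
as long as the hosts themselves, so its synonymous divergence should match
that of host nuclear genes (Adh, Amd, Ddc orthologs here). A TE pair whose
synonymous divergence is significantly LOWER than the hosts' is the signature
of horizontal transfer. Per TE copy pair and host gene, the synonymous
differences and sites of both alignments enter a 2x2 contingency table

        [[Sd_te,   S_te - Sd_te],
         [Sd_gene, S_gene - Sd_gene]]

and a one-tailed Fisher's exact test asks whether the TE's synonymous
difference proportion is deficient. dS values double as molecular-clock
divergence-time estimates via a synonymous rate r (default 0.016
substitutions/site/Myr per lineage): T = dS / 2r.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from httscan.core_io import Config, SequenceRecord
from httscan.distances import DistanceEstimate, PairCounts, ng_distance

logger = logging.getLogger(__name__)

__all__ = [
    "HttTestRecord",
    "ScanSummary",
    "make_contingency",
    "fisher_one_tailed",
    "htt_scan",
    "divergence_time",
]


@dataclass(frozen=True)
class HttTestRecord:
    """One TE-pair vs gene-pair synonymous-divergence contrast."""

    te_id1: str
    te_id2: str
    species1: str
    species2: str
    gene: str
    dS_te: float
    dS_gene: float
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    flagged: bool


@dataclass(frozen=True)
class ScanSummary:
    """Per-gene aggregate of an HTT scan."""

    gene: str
    n_comparisons: int
    n_ds_lower: int
    n_significant: int
    n_skipped: int

    @property
    def pct_significant(self) -> float:
        """100 * n_significant / n_comparisons, rounded to 1 decimal."""
        if self.n_comparisons == 0:
            return math.nan
        return round(100.0 * self.n_significant / self.n_comparisons, 1)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def make_contingency(te: PairCounts,
                     gene: PairCounts) -> tuple[tuple[int, int], tuple[int, int]]:
    """Build the 2x2 synonymous-differences table from NG86 counts.

    Fractional counts are rounded half-away-from-zero; rows are
    (differences, non-differences) for the TE pair then the gene pair.
    """
    if te.S <= 0 or gene.S <= 0:
        raise ValueError("degenerate comparison: zero synonymous sites")
    a = _round_half_away(te.Sd)
    row1 = _round_half_away(te.S) - a
    c = _round_half_away(gene.Sd)
    row2 = _round_half_away(gene.S) - c
    return ((a, row1), (c, row2))


def fisher_one_tailed(table) -> float:
    """One-tailed Fisher's exact p-value for the 'less' alternative on the
    top-left cell.

    With margins fixed, the [0][0] entry is hypergeometric; the p-value sums
    the point masses of all tables whose [0][0] entry is <= the observed one
    (alternative: row-1 success proportion is smaller than row-2's).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("contingency table entries must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("both rows must have positive totals")
    M = a + b + c + d      # population size
    n = a + c              # total successes (column-1 margin)
    N = a + b              # draws (row-1 margin)
    return float(hypergeom.cdf(a, M, n, N))


def divergence_time(dS: float, cfg: Config) -> float:
    """Molecular-clock divergence time in Myr from a pairwise dS.

    Both lineages accumulate substitutions, so by default
    T = dS / (2 * syn_rate_r); with ``clock_per_lineage=False``, T = dS / r.
    """
    if not (dS >= 0.0) or math.isnan(dS):
        raise ValueError(f"dS must be a defined non-negative value, got {dS}")
    divisor = 2.0 * cfg.syn_rate_r if cfg.clock_per_lineage else cfg.syn_rate_r
    return dS / divisor


def htt_scan(
    te_records: list[SequenceRecord],
    gene_alns: dict[str, list[SequenceRecord]],
    cfg: Config,
) -> tuple[list[HttTestRecord], list[ScanSummary]]:
    """Scan all cross-species TE copy pairs against host-gene orthologs.

    For every unordered pair of TE copies from different species and every
    gene with orthologs in both species, NG86 counts for both pairs feed the
    contingency table and the one-tailed test. A comparison is flagged iff
    p < alpha AND dS_te < dS_gene. Same-species pairs are skipped; pairs where
    either dS is undefined are skipped and tallied. Gene alignments must carry
    at most one ortholog per species.

    Returns (records, per-gene summaries); summaries are ordered like
    ``gene_alns`` keys.
    """
    gene_by_species: dict[str, dict[str, SequenceRecord]] = {}
    for gene, recs in gene_alns.items():
        by_sp: dict[str, SequenceRecord] = {}
        for rec in recs:
            if rec.species in by_sp:
                raise ValueError(f"gene {gene}: multiple orthologs for species "
                                 f"{rec.species!r}")
            by_sp[rec.species] = rec
        gene_by_species[gene] = by_sp

    te_dist_cache: dict[tuple[str, str], DistanceEstimate] = {}
    gene_dist_cache: dict[tuple[str, str, str], DistanceEstimate] = {}

    records: list[HttTestRecord] = []
    tallies = {g: {"n": 0, "lower": 0, "sig": 0, "skip": 0} for g in gene_alns}

    for te1, te2 in itertools.combinations(te_records, 2):
        if te1.species == te2.species:
            continue
        key = (te1.id, te2.id)
        if key not in te_dist_cache:
            te_dist_cache[key] = ng_distance(te1.seq, te2.seq)
        te_est = te_dist_cache[key]
        for gene, by_sp in gene_by_species.items():
            g1 = by_sp.get(te1.species)
            g2 = by_sp.get(te2.species)
            if g1 is None or g2 is None:
                logger.debug("no %s orthologs for pair %s/%s",
                             gene, te1.species, te2.species)
                continue
            gkey = (gene, *sorted((te1.species, te2.species)))
            if gkey not in gene_dist_cache:
                gene_dist_cache[gkey] = ng_distance(g1.seq, g2.seq)
            gene_est = gene_dist_cache[gkey]
            if not (te_est.defined and gene_est.defined):
                tallies[gene]["skip"] += 1
                continue
            table = make_contingency(te_est.counts, gene_est.counts)
            p = fisher_one_tailed(table)
            ds_lower = te_est.dS < gene_est.dS
            flagged = (p < cfg.alpha) and ds_lower
            tallies[gene]["n"] += 1
            tallies[gene]["lower"] += int(ds_lower)
            tallies[gene]["sig"] += int(flagged)
            records.append(HttTestRecord(
                te_id1=te1.id, te_id2=te2.id,
                species1=te1.species, species2=te2.species,
                gene=gene, dS_te=te_est.dS, dS_gene=gene_est.dS,
                table=table, p_value=p, flagged=flagged,
            ))

    summaries = [ScanSummary(gene=g, n_comparisons=t["n"],
                             n_ds_lower=t["lower"], n_significant=t["sig"],
                             n_skipped=t["skip"])
                 for g, t in tallies.items()]
    return records, summaries
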