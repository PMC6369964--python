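"""Reading, validation, polarization, and LD-block annotation of GWAS summary statistics.

GWAS effect sizes are reported with respect to an arbitrary reference allele.
For evolutionary analysis we re-orient ("polarize") every effect so that it
describes the *derived* allele: the allele created by mutation, identified by
comparing the two observed alleles with an externally supplied ancestral
allele.  After polarization a variant carries a derived-allele effect size
``beta_derived`` and a derived allele frequency (DAF) strictly inside (0, 1).

Linkage blocks (approximately independent segments of the genome, e.g. the
Berisa-Pickrell blocks) are given as BED-like 0-based half-open intervals and
are the exchangeable unit of the permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default column names for summary-statistic tables
DEFAULT_COLUMN_MAP = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "A1",
    "other_allele": "A2",
    "ancestral_allele": "AA",
    "beta_effect": "BETA",
    "freq_effect": "FREQ",
}

STRAND_AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass(frozen=True)
class RawSummaryRecord:
    """One row of a GWAS summary table, as reported (arbitrary reference allele)."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    ancestral_allele: str
    beta_effect: float
    freq_effect: float

    def validate(self) -> Optional[str]:
        """Return a reason string if the record violates its invariants, else None."""
        if self.effect_allele == self.other_allele:
            return "effect_allele == other_allele"
        if not (0.0 < self.freq_effect < 1.0):
            return "freq_effect outside (0,1)"
        if not np.isfinite(self.beta_effect):
            return "beta_effect not finite"
        if self.pos < 0:
            return "negative position"
        return None


@dataclass(frozen=True)
class PolarizedVariant:
    """A variant oriented to its derived allele."""

    variant_id: str
    chrom: str
    pos: int
    beta_derived: float
    daf: float
    block_id: Optional[int] = None


class LinkageBlockMap:
    """Ordered, per-chromosome disjoint 0-based half-open intervals with block ids."""

    def __init__(self, blocks: Sequence[tuple[str, int, int, int]]):
        blocks = sorted(blocks, key=lambda b: (b[0], b[1]))
        for chrom, start, end, _bid in blocks:
            if not start < end:
                raise ValueError(f"block on {chrom} has start {start} >= end {end}")
        for (c1, s1, e1, _), (c2, s2, e2, _) in zip(blocks, blocks[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError(f"overlapping blocks on chromosome {c1}: "
                                 f"[{s1},{e1}) and [{s2},{e2})")
        self.blocks = list(blocks)
        # per-chromosome sorted interval arrays for O(log n) lookup
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in {b[0] for b in blocks}:
            sub = [b for b in blocks if b[0] == chrom]
            starts = np.array([b[1] for b in sub])
            ends = np.array([b[2] for b in sub])
            ids = np.array([b[3] for b in sub])
            self._by_chrom[chrom] = (starts, ends, ids)

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def max_block_id(self) -> int:
        return max((b[3] for b in self.blocks), default=-1)

    def lookup(self, chrom: str, pos: int) -> Optional[int]:
        """Block id containing 1-based position ``pos``, or None.

        The 1-based GWAS coordinate maps to 0-based offset ``pos - 1``,
        which is tested against the half-open interval [start, end).
        """
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, ids = entry
        p = pos - 1
        i = int(np.searchsorted(starts, p, side="right")) - 1
        if i >= 0 and p < ends[i]:
            return int(ids[i])
        return None


def polarize_record(rec: RawSummaryRecord) -> Optional[PolarizedVariant]:
    """Orient one record to its derived allele; return None if it must be rejected.

    If the ancestral allele equals the non-effect allele, the effect allele is
    the derived allele and the record is already oriented.  If the ancestral
    allele equals the effect allele, the derived allele is the other one: the
    sign of beta flips and the frequency maps to its complement.  Records whose
    ancestral state matches neither allele are unresolvable and rejected
    (logged, not raised).
    """
    reason = rec.validate()
    if reason is not None:
        logger.debug("rejected %s: %s", rec.variant_id, reason)
        return None
    if rec.ancestral_allele == rec.other_allele:
        beta, daf = rec.beta_effect, rec.freq_effect
    elif rec.ancestral_allele == rec.effect_allele:
        beta, daf = -rec.beta_effect, 1.0 - rec.freq_effect
    else:
        logger.debug("rejected %s: ancestral allele %s matches neither %s nor %s",
                     rec.variant_id, rec.ancestral_allele,
                     rec.effect_allele, rec.other_allele)
        return None
    if not (0.0 < daf < 1.0):
        logger.debug("rejected %s: daf %g outside (0,1) after polarization",
                     rec.variant_id, daf)
        return None
    return PolarizedVariant(rec.variant_id, rec.chrom, rec.pos, beta, daf)


class PolarizationSummary(NamedTuple):
    n_input: int
    n_polarized: int
    n_rejected_ancestral: int
    n_rejected_invalid: int
    n_rejected_ambiguous: int


def polarize_records(
    records: Iterable[RawSummaryRecord],
    exclude_strand_ambiguous: bool = False,
) -> tuple[list[PolarizedVariant], PolarizationSummary]:
    """Polarize a batch of records, counting each class of rejection.

    Strand-ambiguous sites (A/T and C/G) are kept by default; set
    ``exclude_strand_ambiguous`` to drop them.
    """
    out: list[PolarizedVariant] = []
    n_in = n_anc = n_bad = n_amb = 0
    for rec in records:
        n_in += 1
        if exclude_strand_ambiguous and frozenset(
            {rec.effect_allele, rec.other_allele}
        ) in STRAND_AMBIGUOUS_PAIRS:
            n_amb += 1
            continue
        if rec.validate() is not None:
            n_bad += 1
            continue
        pv = polarize_record(rec)
        if pv is None:
            n_anc += 1
            continue
        out.append(pv)
    summary = PolarizationSummary(n_in, len(out), n_anc, n_bad, n_amb)
    logger.info("polarized %d/%d records (%d unresolvable ancestral state, "
                "%d invalid, %d strand-ambiguous excluded)",
                summary.n_polarized, summary.n_input, n_anc, n_bad, n_amb)
    return out, summary


def assign_blocks(
    variants: Sequence[PolarizedVariant], blocks: LinkageBlockMap
) -> list[PolarizedVariant]:
    """Attach a block id to every variant.

    Variants falling in no block receive fresh singleton block ids (one per
    variant) so the downstream permutation treats each as its own independent
    unit.  Singleton ids are allocated in genomic order, so the assignment does
    not depend on the input ordering of the variant list.
    """
    hits = [blocks.lookup(v.chrom, v.pos) for v in variants]
    unmatched = [i for i, h in enumerate(hits) if h is None]
    if unmatched:
        logger.info("%d of %d variants fall outside all blocks; "
                    "assigning singleton blocks", len(unmatched), len(variants))
        next_id = blocks.max_block_id + 1
        for i in sorted(unmatched, key=lambda i: (variants[i].chrom, variants[i].pos)):
            hits[i] = next_id
            next_id += 1
    return [replace(v, block_id=h) for v, h in zip(variants, hits)]


def read_summary_table(
    path,
    column_map: Optional[dict[str, str]] = None,
    sep: str = r"\s+",
) -> tuple[list[RawSummaryRecord], int]:
    """Read a delimited summary-statistic table into records.

    Returns (records, n_skipped).  Malformed rows (non-numeric beta/frequency,
    frequency outside (0,1), identical alleles) are counted and skipped.
    A missing required column raises ``KeyError``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise KeyError(f"summary table {path} is missing required columns: {missing}")
    records: list[RawSummaryRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        d = {field: getattr(row, col) for field, col in cmap.items()}
        try:
            rec = RawSummaryRecord(
                variant_id=str(d["variant_id"]),
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                effect_allele=str(d["effect_allele"]).upper(),
                other_allele=str(d["other_allele"]).upper(),
                ancestral_allele=str(d["ancestral_allele"]).upper(),
                beta_effect=float(d["beta_effect"]),
                freq_effect=float(d["freq_effect"]),
            )
        except (TypeError, ValueError):
            n_skipped += 1
            continue
        if rec.validate() is not None:
            n_skipped += 1
            continue
        records.append(rec)
    logger.info("read %d records from %s (%d malformed rows skipped)",
                len(records), path, n_skipped)
    return records, n_skipped


def read_block_bed(path) -> LinkageBlockMap:
    """Read a BED-like block file (chrom, start, end[, block_id]).

    When the 4th column is absent, ids are assigned by file order.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"block file {path} needs at least 3 columns")
    blocks = []
    for i, row in enumerate(df.itertuples(index=False)):
        bid = int(row[3]) if df.shape[1] >= 4 else i
        blocks.append((str(row[0]), int(row[1]), int(row[2]), bid))
    return LinkageBlockMap(blocks)


def write_polarized_table(variants: Sequence[PolarizedVariant], path) -> None:
    """Write polarized variants as TSV (SNP, CHR, POS, BETA_DERIVED, DAF, BLOCK)."""
    df = variants_to_frame(variants)
    df.to_csv(path, sep="\t", index=False)


def variants_to_frame(variants: Sequence[PolarizedVariant]) -> pd.DataFrame:
    return pd.DataFrame({
        "SNP": [v.variant_id for v in variants],
        "CHR": [v.chrom for v in variants],
        "POS": [v.pos for v in variants],
        "BETA_DERIVED": [v.beta_derived for v in variants],
        "DAF": [v.daf for v in variants],
        "BLOCK": [-1 if v.block_id is None else v.block_id for v in variants],
    })


def read_polarized_table(path) -> list[PolarizedVariant]:
    """Read back a table written by :func:`write_polarized_table`."""
    df = pd.read_csv(path, sep="\t")
    return [
        PolarizedVariant(str(r.SNP), str(r.CHR), int(r.POS),
                         float(r.BETA_DERIVED), float(r.DAF),
                         None if int(r.BLOCK) < 0 else int(r.BLOCK))
        for r in df.itertuples(index=False)
    ]
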