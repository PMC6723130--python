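"""Anchor consensus reads to probe regions and call substitutions.

The targets are a few dozen known ~150 bp regions, so a seed-and-verify
aligner over a precomputed 20-mer index of the panel (both strands) is
exact and deterministic; no external aligner is involved.  Calls are
per-position, per-alt substitutions supported by a minimum number of
independent captures (default 5) -- the rule that removes first-round
PCR errors, which are confined to single captures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from ._seq import N
from .consensus import ConsensusSet
from .errors import DataError, EdgeContextError
from .panel import Probe, ProbePanel

SEED_LEN = 20

CALL_COLUMNS = [
    "chrom", "pos", "probe_id", "offset", "ref", "alt",
    "supporting_captures", "covering_captures", "vaf", "context",
]


@dataclass
class AlignedBatch:
    """Consensus reads of one probe, laid out in plus-strand region space."""

    probe: Probe
    seqs: np.ndarray  # (n, region_len) codes, N-padded outside the aligned span
    support: np.ndarray
    n_mismatches: np.ndarray


@dataclass
class AlignedConsensusSet:
    batches: dict[str, AlignedBatch] = field(default_factory=dict)
    n_aligned: int = 0
    n_rejected: int = 0

    def batch(self, probe_id: str) -> AlignedBatch:
        return self.batches[probe_id]


class PanelIndex:
    """Exact 20-mer lookup over all panel regions, both strands."""

    def __init__(self, panel: ProbePanel, seed_len: int = SEED_LEN):
        self.panel = panel
        self.seed_len = seed_len
        self.kmers: dict[bytes, list[tuple[str, int, str]]] = {}
        for probe in panel:
            if probe.length < seed_len:
                raise DataError(
                    f"probe {probe.probe_id} shorter than seed length {seed_len}"
                )
            fwd = probe.codes
            rev = _seq.revcomp(fwd)
            for off in range(probe.length - seed_len + 1):
                self.kmers.setdefault(
                    fwd[off : off + seed_len].tobytes(), []
                ).append((probe.probe_id, off, "forward"))
                self.kmers.setdefault(
                    rev[off : off + seed_len].tobytes(), []
                ).append((probe.probe_id, off, "reverse"))


def _best_placement(
    codes: np.ndarray, index: PanelIndex, max_mismatch: int
) -> tuple[str, int, str, int] | None:
    """(probe_id, offset, orientation, mismatches) of the best seed hit."""
    width = codes.shape[0]
    seed_len = index.seed_len
    candidates: set[tuple[str, int, str]] = set()
    # try seeds at a few phases so an N or an error cannot kill the lookup
    for seed_start in range(0, width - seed_len + 1, seed_len):
        window = codes[seed_start : seed_start + seed_len]
        if (window >= N).any():
            continue
        for probe_id, kmer_off, orientation in index.kmers.get(
            window.tobytes(), ()
        ):
            # read-start offset in the strand space the k-mer was indexed in
            candidates.add((probe_id, kmer_off - seed_start, orientation))
    best: tuple[str, int, str, int] | None = None
    for probe_id, offset, orientation in sorted(candidates):
        probe = index.panel[probe_id]
        if offset < 0 or offset + width > probe.length:
            continue
        region = probe.codes
        if orientation == "forward":
            oriented = codes
            region_offset = offset
        else:
            oriented = _seq.revcomp(codes)
            region_offset = probe.length - offset - width
        segment = region[region_offset : region_offset + width]
        mismatches = int(((oriented != segment) & (oriented < N)).sum())
        if mismatches <= max_mismatch and (best is None or mismatches < best[3]):
            best = (probe_id, region_offset, orientation, mismatches)
    return best


def align_consensus(
    consensus: ConsensusSet | list,
    panel: ProbePanel,
    max_mismatch: int = 10,
    index: PanelIndex | None = None,
) -> AlignedConsensusSet:
    """Place every consensus read inside its probe region.

    Identical sequences are aligned once and their placements reused.
    Reverse-orientation reads are stored reverse-complemented, so batch
    matrices are always in plus-strand space.  Reads with no seed hit or
    too many mismatches are rejected (QC-counted): this is what excludes
    variants outside the probed regions.
    """
    if index is None:
        index = PanelIndex(panel)
    result = AlignedConsensusSet()
    per_probe: dict[str, tuple[list[np.ndarray], list[int], list[int]]] = {
        p.probe_id: ([], [], []) for p in panel
    }
    for batch in getattr(consensus, "batches", consensus):
        seqs, support = batch.seqs, batch.support
        if seqs.shape[0] == 0:
            continue
        void = _seq.rows_as_void(seqs)
        uniq, inverse = np.unique(void, return_inverse=True)
        width = seqs.shape[1]
        placements: list[tuple[str, int, str, int] | None] = []
        for u in range(uniq.shape[0]):
            codes = np.frombuffer(uniq[u].tobytes(), dtype=np.uint8)
            placements.append(_best_placement(codes, index, max_mismatch))
        by_placement: dict[tuple[str, int, str, int], list[int]] = {}
        for u, placement in enumerate(placements):
            if placement is None:
                continue
            by_placement.setdefault(placement, []).append(u)
        placed = np.zeros(uniq.shape[0], dtype=bool)
        for placement in sorted(by_placement):
            probe_id, offset, orientation, mismatches = placement
            probe = panel[probe_id]
            uniq_ids = np.array(by_placement[placement])
            placed[uniq_ids] = True
            sel = np.flatnonzero(np.isin(inverse, uniq_ids))
            oriented = seqs[sel]
            if orientation == "reverse":
                oriented = _seq.revcomp(oriented)
            rows = np.full((sel.size, probe.length), N, dtype=np.uint8)
            rows[:, offset : offset + width] = oriented
            bucket = per_probe[probe_id]
            bucket[0].append(rows)
            bucket[1].append(support[sel].astype(np.int64))
            bucket[2].append(np.full(sel.size, mismatches, dtype=np.int64))
            result.n_aligned += sel.size
        result.n_rejected += int((~placed[inverse]).sum())
    for probe in panel:
        rows, sup, mm = per_probe[probe.probe_id]
        if rows:
            result.batches[probe.probe_id] = AlignedBatch(
                probe,
                np.concatenate(rows),
                np.concatenate(sup),
                np.concatenate(mm),
            )
    return result


# ---------------------------------------------------------------------------
# pileup and calling


@dataclass
class Pileup:
    """Per-probe (region_len, 5) base counts over aligned consensus reads."""

    counts: dict[str, np.ndarray]
    panel: ProbePanel

    def depth(self, probe_id: str) -> np.ndarray:
        """Non-N covering captures per position."""
        return self.counts[probe_id][:, :4].sum(axis=1)


def build_pileup(aligned: AlignedConsensusSet, panel: ProbePanel) -> Pileup:
    counts = {
        probe.probe_id: np.zeros((probe.length, 5), dtype=np.int64)
        for probe in panel
    }
    for probe_id, batch in aligned.batches.items():
        width = batch.probe.length
        flat = np.arange(width, dtype=np.int64)[None, :] * 5 + batch.seqs
        counts[probe_id] += np.bincount(
            flat.ravel(), minlength=width * 5
        ).reshape(width, 5)
    return Pileup(counts, panel)


def call_variants(
    pileup: Pileup, panel: ProbePanel, min_capture_support: int = 5
) -> pd.DataFrame:
    """Emit one row per (position, alt) with enough independent captures.

    VAF = supporting captures / non-N covering captures.  Germline
    heterozygotes appear at VAF ~ 0.5 and are retained; significance is
    decided later by the background stage.
    """
    rows = []
    for probe in panel:
        counts = pileup.counts[probe.probe_id]
        depth = counts[:, :4].sum(axis=1)
        ref_codes = probe.codes
        for alt_code in range(4):
            alt_counts = counts[:, alt_code]
            hits = np.flatnonzero(
                (alt_counts >= min_capture_support) & (ref_codes != alt_code)
            )
            for off in hits:
                pos = probe.start + int(off)
                try:
                    context = panel.trinucleotide_context(probe.chrom, pos)
                except EdgeContextError:
                    context = "."
                rows.append(
                    {
                        "chrom": probe.chrom,
                        "pos": pos,
                        "probe_id": probe.probe_id,
                        "offset": int(off),
                        "ref": probe.region_seq[off],
                        "alt": _seq.BASES[alt_code],
                        "supporting_captures": int(alt_counts[off]),
                        "covering_captures": int(depth[off]),
                        "vaf": float(alt_counts[off]) / float(depth[off]),
                        "context": context,
                    }
                )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.sort_values(["chrom", "pos", "alt"], ignore_index=True)


# ---------------------------------------------------------------------------
# VCF I/O


def _vcf_header(panel: ProbePanel) -> "pysam.VariantHeader":
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##source=umivar")
    header.add_line(f"##reference={panel.genome_label}")
    chrom_max: dict[str, int] = {}
    for probe in panel:
        chrom_max[probe.chrom] = max(chrom_max.get(probe.chrom, 0), probe.end)
    for chrom, end in sorted(chrom_max.items()):
        header.contigs.add(chrom, length=end + 1)
    header.info.add("SUP", 1, "Integer", "Supporting captures")
    header.info.add("DPU", 1, "Integer", "Covering captures (non-N)")
    header.info.add("VAF", 1, "Float", "Variant allele frequency")
    header.info.add("CTX", 1, "String", "Trinucleotide context")
    header.info.add("SIG", 1, "String", "Significance vs background")
    return header


def write_vcf(calls: pd.DataFrame, panel: ProbePanel, path) -> None:
    """Write calls as minimal VCF 4.2 (positions 1-based, plus strand)."""
    import pysam

    header = _vcf_header(panel)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in calls.itertuples(index=False):
            record = out.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.ref, row.alt),
            )
            record.info["SUP"] = int(row.supporting_captures)
            record.info["DPU"] = int(row.covering_captures)
            record.info["VAF"] = float(row.vaf)
            record.info["CTX"] = row.context if row.context != "." else "NA"
            sig = getattr(row, "significant", None)
            if sig is not None and not pd.isna(sig):
                record.info["SIG"] = getattr(row, "filter_route", "") or str(bool(sig))
            out.write(record)


def read_vcf(path, panel: ProbePanel) -> pd.DataFrame:
    """Read a VCF written by :func:`write_vcf` back into a call table."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            hit = panel.locate(record.chrom, record.pos)
            probe_id = hit[0].probe_id if hit else "."
            offset = hit[1] if hit else -1
            context = record.info.get("CTX", "NA")
            rows.append(
                {
                    "chrom": record.chrom,
                    "pos": record.pos,
                    "probe_id": probe_id,
                    "offset": offset,
                    "ref": record.ref,
                    "alt": record.alts[0],
                    "supporting_captures": int(record.info["SUP"]),
                    "covering_captures": int(record.info["DPU"]),
                    "vaf": float(record.info["VAF"]),
                    "context": "." if context == "NA" else context,
                }
            )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)
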