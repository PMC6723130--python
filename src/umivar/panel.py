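"""Targeted probe panel: the anchor for every downstream stage.

A panel is a small set (tens) of ~150 bp amplicon regions with known
reference sequence and genomic coordinates.  Genomic coordinates are
1-based inclusive at the file and VCF boundary; everything internal works
with 0-based offsets into ``region_seq``.  Probes on the minus strand
still store ``region_seq`` as the plus strand, so all variant reporting
is plus-strand; complement collapsing happens only at spectrum time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from .errors import EdgeContextError, PanelError

_VALID_SEQ = re.compile(r"^[ACGT]+$")

PANEL_COLUMNS = ["probe_id", "chrom", "start", "end", "strand", "region_seq"]


@dataclass(frozen=True)
class Probe:
    """One targeted amplicon region.

    ``start``/``end`` are genomic, 1-based inclusive; ``region_seq`` is
    the plus-strand reference sequence of the region.
    """

    probe_id: str
    chrom: str
    start: int
    end: int
    strand: str
    region_seq: str
    umi_len: int = 12
    sample_index_len: int = 16

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise PanelError(f"{self.probe_id}: strand must be '+' or '-'")
        if self.end < self.start:
            raise PanelError(f"{self.probe_id}: end < start")
        if len(self.region_seq) != self.end - self.start + 1:
            raise PanelError(
                f"{self.probe_id}: region_seq length {len(self.region_seq)} does not "
                f"match {self.chrom}:{self.start}-{self.end}"
            )
        if not _VALID_SEQ.match(self.region_seq):
            raise PanelError(f"{self.probe_id}: region_seq contains non-ACGT characters")
        if self.umi_len <= 0:
            raise PanelError(f"{self.probe_id}: umi_len must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def codes(self) -> np.ndarray:
        """Region sequence as a uint8 code array (cached on first use)."""
        cached = _PROBE_CODES.get(id(self))
        if cached is None:
            cached = _seq.encode(self.region_seq)
            _PROBE_CODES[id(self)] = cached
        return cached

    def offset_of(self, pos: int) -> int:
        """0-based offset of genomic position ``pos`` inside the region."""
        if not self.start <= pos <= self.end:
            raise PanelError(f"{self.probe_id}: position {pos} outside region")
        return pos - self.start


# id(Probe) -> encoded region; Probe is frozen so this is safe for the
# lifetime of the object (worst case: a dead id is re-encoded).
_PROBE_CODES: dict[int, np.ndarray] = {}


@dataclass
class ProbePanel:
    """Ordered, non-overlapping collection of probes."""

    probes: list[Probe]
    genome_label: str = "custom"
    _by_id: dict[str, Probe] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: dict[str, Probe] = {}
        for probe in self.probes:
            if probe.probe_id in seen:
                raise PanelError(f"duplicate probe_id {probe.probe_id!r}")
            seen[probe.probe_id] = probe
        by_chrom: dict[str, list[Probe]] = {}
        for probe in self.probes:
            by_chrom.setdefault(probe.chrom, []).append(probe)
        for chrom, group in by_chrom.items():
            group = sorted(group, key=lambda p: p.start)
            for left, right in zip(group, group[1:]):
                if right.start <= left.end:
                    raise PanelError(
                        f"probes {left.probe_id} and {right.probe_id} overlap on {chrom}"
                    )
        self._by_id = seen

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def __getitem__(self, probe_id: str) -> Probe:
        return self._by_id[probe_id]

    def locate(self, chrom: str, pos: int) -> tuple[Probe, int] | None:
        """Probe containing 1-based ``pos`` and the 0-based offset, or None."""
        for probe in self.probes:
            if probe.chrom == chrom and probe.start <= pos <= probe.end:
                return probe, pos - probe.start
        return None

    def ref_base(self, chrom: str, pos: int) -> str:
        hit = self.locate(chrom, pos)
        if hit is None:
            raise PanelError(f"{chrom}:{pos} is not probed")
        probe, off = hit
        return probe.region_seq[off]

    def trinucleotide_context(self, chrom: str, pos: int) -> str:
        """Plus-strand 5' base + reference base + 3' base around ``pos``.

        Both neighbours must lie inside the same probe region; context at
        a region edge is undefined for this assay.
        """
        hit = self.locate(chrom, pos)
        if hit is None:
            raise PanelError(f"{chrom}:{pos} is not probed")
        probe, off = hit
        if off == 0 or off == probe.length - 1:
            raise EdgeContextError(
                f"{chrom}:{pos} sits at the edge of probe {probe.probe_id}"
            )
        return probe.region_seq[off - 1 : off + 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "probe_id": p.probe_id,
                    "chrom": p.chrom,
                    "start": p.start,
                    "end": p.end,
                    "strand": p.strand,
                    "region_seq": p.region_seq,
                }
                for p in self.probes
            ],
            columns=PANEL_COLUMNS,
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_panel(path, umi_len: int = 12, sample_index_len: int = 16,
               genome_label: str = "custom") -> ProbePanel:
    """Load a panel from a tab-separated file.

    Required columns: probe_id, chrom, start, end, strand, region_seq,
    with 1-based inclusive coordinates.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "probe_id": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise PanelError(f"cannot read panel file {path}: {exc}") from exc
    missing = [c for c in PANEL_COLUMNS if c not in table.columns]
    if missing:
        raise PanelError(f"panel file {path} lacks columns: {missing}")
    probes = [
        Probe(
            probe_id=row.probe_id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            region_seq=str(row.region_seq).upper(),
            umi_len=umi_len,
            sample_index_len=sample_index_len,
        )
        for row in table.itertuples(index=False)
    ]
    return ProbePanel(probes, genome_label=genome_label)


def load_bed_fasta(bed_path, fasta_path, umi_len: int = 12,
                   genome_label: str = "custom") -> ProbePanel:
    """Convenience loader: BED intervals (0-based half-open) + reference FASTA."""
    from pyfaidx import Fasta

    ref = Fasta(str(fasta_path))
    probes = []
    with open(bed_path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelError(f"{bed_path}:{line_no}: need >= 3 BED columns")
            chrom, bed_start, bed_end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"probe{line_no}"
            strand = fields[5] if len(fields) > 5 else "+"
            seq = str(ref[chrom][bed_start:bed_end]).upper()
            probes.append(
                Probe(
                    probe_id=name,
                    chrom=chrom,
                    start=bed_start + 1,
                    end=bed_end,
                    strand=strand,
                    region_seq=seq,
                    umi_len=umi_len,
                )
            )
    return ProbePanel(probes, genome_label=genome_label)
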