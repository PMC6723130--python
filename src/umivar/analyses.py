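"""Validation analyses built on the calling stack.

These are the assay's standard sanity experiments, packaged as reusable
procedures: phasing rare variants against heterozygous SNPs (real
somatic variants ride one allele, artifacts ride both), exploiting
linked SNPs to discard chimeric or error-bearing reads, recovering a
dilution series, and tracking variants across longitudinal samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from . import _seq
from ._seq import N
from .background import BackgroundModel, SubKey, filter_variants
from .callvars import AlignedBatch, AlignedConsensusSet, Pileup
from .errors import DataError, FilterError, PhasingError
from .panel import ProbePanel


# ---------------------------------------------------------------------------
# allele phasing


@dataclass
class PhasePartition:
    """Consensus reads split by the allele they carry at one het SNP.

    ``association`` has one row per other variant with pooled support:
    its VAF inside the alt-allele bin, inside the ref-allele bin, a
    two-proportion test of equal association and its BH-adjusted q-value.
    Reads with N at the SNP join neither bin.
    """

    snp: SubKey
    alt_reads: np.ndarray  # row indices into the probe's aligned batch
    ref_reads: np.ndarray
    association: pd.DataFrame


def phase_by_het_snp(
    aligned: AlignedConsensusSet,
    snp: SubKey,
    panel: ProbePanel,
    min_support: int = 5,
) -> PhasePartition:
    """Partition a probe's consensus reads by the base at a het SNP.

    A genuinely somatic variant shows a strongly asymmetric VAF between
    the two bins (it lives on one haplotype); library artifacts associate
    evenly.  Raises :class:`PhasingError` when the minor allele has fewer
    than ``min_support`` captures.
    """
    hit = panel.locate(snp.chrom, snp.pos)
    if hit is None:
        raise FilterError(f"SNP {snp.chrom}:{snp.pos} outside panel")
    probe, off = hit
    if probe.probe_id not in aligned.batches:
        raise PhasingError(f"no aligned reads for probe {probe.probe_id}")
    batch = aligned.batches[probe.probe_id]
    ref_code = _seq.encode(snp.ref)[0]
    alt_code = _seq.encode(snp.alt)[0]
    bases = batch.seqs[:, off]
    alt_reads = np.flatnonzero(bases == alt_code)
    ref_reads = np.flatnonzero(bases == ref_code)
    if min(alt_reads.size, ref_reads.size) < min_support:
        raise PhasingError(
            f"{snp.chrom}:{snp.pos} not heterozygous here: allele depths "
            f"{ref_reads.size}/{alt_reads.size} below {min_support}"
        )
    association = _bin_association(
        batch, probe, alt_reads, ref_reads, skip_offset=off,
        min_support=min_support,
    )
    return PhasePartition(snp, alt_reads, ref_reads, association)


def _bin_counts(batch: AlignedBatch, rows: np.ndarray) -> np.ndarray:
    width = batch.probe.length
    flat = np.arange(width, dtype=np.int64)[None, :] * 5 + batch.seqs[rows]
    return np.bincount(flat.ravel(), minlength=width * 5).reshape(width, 5)


def _bin_association(
    batch: AlignedBatch,
    probe,
    bin_a: np.ndarray,
    bin_b: np.ndarray,
    skip_offset: int,
    min_support: int,
) -> pd.DataFrame:
    counts_a = _bin_counts(batch, bin_a)
    counts_b = _bin_counts(batch, bin_b)
    depth_a = counts_a[:, :4].sum(axis=1)
    depth_b = counts_b[:, :4].sum(axis=1)
    rows = []
    for off in range(probe.length):
        if off == skip_offset:
            continue
        ref_code = probe.codes[off]
        for alt_code in range(4):
            if alt_code == ref_code:
                continue
            ca, cb = int(counts_a[off, alt_code]), int(counts_b[off, alt_code])
            if ca + cb < min_support:
                continue
            da, db = int(depth_a[off]), int(depth_b[off])
            _, pval = proportions_ztest([ca, cb], [da, db])
            rows.append(
                {
                    "chrom": probe.chrom,
                    "pos": probe.start + off,
                    "ref": probe.region_seq[off],
                    "alt": _seq.BASES[alt_code],
                    "count_a": ca,
                    "depth_a": da,
                    "vaf_a": ca / da if da else 0.0,
                    "count_b": cb,
                    "depth_b": db,
                    "vaf_b": cb / db if db else 0.0,
                    "pooled_vaf": (ca + cb) / (da + db),
                    "pval": float(pval) if np.isfinite(pval) else 1.0,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "count_a", "depth_a", "vaf_a",
                 "count_b", "depth_b", "vaf_b", "pooled_vaf", "pval"],
    )
    if len(table):
        table["qval"] = multipletests(table["pval"], method="fdr_bh")[1]
    else:
        table["qval"] = pd.Series(dtype=float)
    return table


# ---------------------------------------------------------------------------
# linked-SNP error elimination


def linked_snp_filter(
    aligned: AlignedConsensusSet,
    phased_snps: list[SubKey],
    panel: ProbePanel,
) -> tuple[AlignedConsensusSet, pd.DataFrame]:
    """Keep only reads consistent with a phased SNP haplotype.

    With >= 2 het SNPs known to sit on one haplotype of one probe region,
    a correct consensus read carries either all of their alt alleles or
    none; anything else (including N at a listed site) is an error or a
    chimera and is discarded.  Returns the filtered set plus a per-SNP
    before/after VAF report.
    """
    if len(phased_snps) < 2:
        raise FilterError("need >= 2 phased SNPs")
    probes = set()
    offsets = []
    alt_codes = []
    ref_codes = []
    for snp in phased_snps:
        hit = panel.locate(snp.chrom, snp.pos)
        if hit is None:
            raise FilterError(f"SNP {snp.chrom}:{snp.pos} outside panel")
        probe, off = hit
        probes.add(probe.probe_id)
        offsets.append(off)
        alt_codes.append(int(_seq.encode(snp.alt)[0]))
        ref_codes.append(int(_seq.encode(snp.ref)[0]))
    if len(probes) != 1:
        raise FilterError("phased SNPs span multiple probes")
    probe_id = probes.pop()
    if probe_id not in aligned.batches:
        raise DataError(f"no aligned reads for probe {probe_id}")
    batch = aligned.batches[probe_id]
    bases = batch.seqs[:, offsets]  # (n_reads, n_snps)
    all_alt = (bases == np.array(alt_codes)[None, :]).all(axis=1)
    all_ref = (bases == np.array(ref_codes)[None, :]).all(axis=1)
    keep = all_alt | all_ref

    def _snp_vafs(seqs: np.ndarray) -> list[float]:
        out = []
        for off, alt_code in zip(offsets, alt_codes):
            col = seqs[:, off]
            depth = int((col < N).sum())
            out.append(int((col == alt_code).sum()) / depth if depth else 0.0)
        return out

    before = _snp_vafs(batch.seqs)
    after = _snp_vafs(batch.seqs[keep])
    report = pd.DataFrame(
        {
            "chrom": [s.chrom for s in phased_snps],
            "pos": [s.pos for s in phased_snps],
            "ref": [s.ref for s in phased_snps],
            "alt": [s.alt for s in phased_snps],
            "vaf_before": before,
            "vaf_after": after,
            "reads_before": batch.seqs.shape[0],
            "reads_after": int(keep.sum()),
        }
    )
    filtered = AlignedConsensusSet(
        batches=dict(aligned.batches),
        n_aligned=aligned.n_aligned - int((~keep).sum()),
        n_rejected=aligned.n_rejected,
    )
    filtered.batches[probe_id] = AlignedBatch(
        batch.probe,
        batch.seqs[keep],
        batch.support[keep],
        batch.n_mismatches[keep],
    )
    return filtered, report


# ---------------------------------------------------------------------------
# dilution series


def evaluate_dilution(
    call_sets: list[pd.DataFrame],
    spiked: SubKey,
    dilutions: list[float],
    model: BackgroundModel,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Recovery of a serially diluted heterozygous variant.

    ``expected_vaf`` is dilution/2 (a het allele is one of two); observed
    is 0 when the call is absent; ``detected`` means the call exists and
    is significant against the background model.
    """
    if len(call_sets) != len(dilutions):
        raise DataError("one call set per dilution point required")
    rows = []
    for dilution, calls in zip(dilutions, call_sets):
        if not 0.0 < dilution <= 1.0:
            raise DataError(f"dilution {dilution} outside (0, 1]")
        mask = (
            (calls["chrom"] == spiked.chrom)
            & (calls["pos"] == spiked.pos)
            & (calls["alt"] == spiked.alt)
        )
        observed = 0.0
        detected = False
        if mask.any():
            flagged = filter_variants(calls.loc[mask], model, alpha)
            observed = float(flagged["vaf"].iloc[0])
            detected = bool(flagged["significant"].iloc[0])
        rows.append(
            {
                "nominal_dilution": dilution,
                "expected_vaf": dilution / 2.0,
                "observed_vaf": observed,
                "detected": detected,
            }
        )
    return pd.DataFrame(rows)


def dilution_loglog_slope(points: pd.DataFrame) -> float:
    """Slope of log observed vs log expected VAF over the detected points."""
    detected = points[points["detected"] & (points["observed_vaf"] > 0)]
    if len(detected) < 2:
        raise DataError("need >= 2 detected dilution points for a slope")
    slope = np.polyfit(
        np.log10(detected["expected_vaf"]), np.log10(detected["observed_vaf"]), 1
    )[0]
    return float(slope)


# ---------------------------------------------------------------------------
# longitudinal tracking


def track_variants(
    call_sets: list[pd.DataFrame],
    model: BackgroundModel,
    alpha: float | None = None,
    pileups: list[Pileup] | None = None,
) -> pd.DataFrame:
    """VAF trajectories of all variants significant at any timepoint.

    Call sets must be ordered by sampling time.  Undetected timepoints
    report VAF 0 with ``covered`` saying whether the position had any
    capture depth there (always True when pileups are not supplied but
    the sample produced calls on that probe).  ``emergent`` marks keys
    absent at baseline but significant later -- the relapse-driver
    signature.
    """
    if len(call_sets) < 2:
        raise DataError("need >= 2 timepoints")
    flagged_sets = [filter_variants(c, model, alpha) for c in call_sets]
    tracked: dict[SubKey, dict] = {}
    for t, flagged in enumerate(flagged_sets):
        for row in flagged.itertuples(index=False):
            if not row.significant:
                continue
            key = SubKey(row.chrom, int(row.pos), row.ref, row.alt)
            tracked.setdefault(key, {"first_significant": t})
    rows = []
    for key in sorted(tracked):
        emergent = tracked[key]["first_significant"] > 0
        for t, flagged in enumerate(flagged_sets):
            mask = (
                (flagged["chrom"] == key.chrom)
                & (flagged["pos"] == key.pos)
                & (flagged["alt"] == key.alt)
            )
            if mask.any():
                vaf = float(flagged.loc[mask, "vaf"].iloc[0])
                significant = bool(flagged.loc[mask, "significant"].iloc[0])
                covered = True
            else:
                vaf = 0.0
                significant = False
                if pileups is not None:
                    hit = pileups[t].panel.locate(key.chrom, key.pos)
                    covered = bool(
                        hit is not None
                        and pileups[t].depth(hit[0].probe_id)[hit[1]] > 0
                    )
                else:
                    probe_ids = call_sets[t]["probe_id"]
                    covered = bool(
                        (call_sets[t]["chrom"] == key.chrom).any() or len(probe_ids)
                    )
            rows.append(
                {
                    "chrom": key.chrom,
                    "pos": key.pos,
                    "ref": key.ref,
                    "alt": key.alt,
                    "timepoint": t,
                    "vaf": vaf,
                    "significant": significant,
                    "covered": covered,
                    "emergent": emergent,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "timepoint", "vaf",
                 "significant", "covered", "emergent"],
    )
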