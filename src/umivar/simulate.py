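"""Ground-truthed library simulator.

Emulates the full wet-lab stack for a barcoded amplicon capture assay:

* diploid template molecules captured one single strand at a time, each
  tagged with two fresh random 12-base UMIs,
* pre-amplification template damage with position- and substitution-
  specific rates (the physical origin of the position-specific error
  background),
* a founding synthesis ("first round") whose errors propagate to every
  read of the capture, making them indistinguishable from endogenous
  variants at the capture level,
* exponential PCR as a branching doubling process (population capped by
  uniform subsampling so 29 cycles stays tractable); an error arising in
  cycle k >= 2 descends to a 2**-k fraction of the final pool (25% for
  round 2, matching the duplex founder geometry),
* fully overlapping paired-end reads with independent per-base, per-mate
  sequencing errors.

Every molecule, error and read is recorded in :class:`SimTruth`, so the
consensus, calling and background stages can be validated base by base
without any external data.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _seq
from ._seq import A, C, G, N, T
from .errors import ConfigError, SimSpecError
from .panel import Probe, ProbePanel

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class VariantSpec:
    """A variant to plant in the simulated sample.

    ``vaf`` is the fraction of captured alleles carrying the variant.
    Germline variants are carried by every molecule of their haplotype
    (so linked germline SNPs co-occur on reads); somatic variants are
    carried by a Binomial(captures, vaf) subset which is pinned to
    ``haplotype`` so phasing behaves like a real clonal expansion.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    haplotype: str = "A"
    germline: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ConfigError(f"variant VAF {self.vaf} outside [0, 1]")
        if self.haplotype not in ("A", "B"):
            raise ConfigError("haplotype must be 'A' or 'B'")
        if self.germline and abs(self.vaf - 0.5) > 1e-12:
            raise ConfigError("germline heterozygous variants must have vaf 0.5")


from .contexts import (  # noqa: F401  (re-exported: profile helpers use them)
    SUBSTITUTION_CLASSES,
    collapse_context,
    collapse_substitution,
)


@dataclass(frozen=True)
class DamageProfile:
    """Per-(probe, offset, alt) template damage rates.

    Damage here stands for the ex-vivo lesions (oxidation, deamination,
    thermal damage) acquired by template DNA before or during the first
    synthesis: each lesion converts a whole capture, so its control-sample
    VAF directly reflects the position-specific rate.  Rates are sparse:
    most keys are "cold" (rate 0); a class-dependent minority are "hot",
    which reproduces the observed position-specific background structure
    (C>T-dominated, CpG-enriched, T>G almost never hot).
    """

    rates: dict[tuple[str, int, int], float]  # (probe_id, offset, alt_code) -> rate

    def perturb(self, seed: int, sigma: float = 0.5) -> "DamageProfile":
        """Lognormal per-key jitter: the same assay run in another experiment."""
        rng = np.random.default_rng(seed)
        keys = sorted(self.rates)
        factors = rng.lognormal(0.0, sigma, len(keys))
        return DamageProfile({k: self.rates[k] * f for k, f in zip(keys, factors)})


#: probability that a (position, alt) key is a damage hotspot, by class
DEFAULT_HOT_PROBS = {
    "C>T": 0.12,
    "C>A": 0.06,
    "T>C": 0.05,
    "C>G": 0.02,
    "T>A": 0.015,
    "T>G": 0.004,
}
CPG_CT_HOT_PROB = 0.45


def make_damage_profile(
    panel: ProbePanel,
    seed: int,
    hot_rate_median: float = 5e-4,
    hot_rate_sigma: float = 0.5,
    hot_probs: dict[str, float] | None = None,
    cpg_ct_hot_prob: float = CPG_CT_HOT_PROB,
) -> DamageProfile:
    """Draw a position-specific damage landscape for a panel.

    The landscape is a property of the assay (probe chemistry and
    library preparation), so samples from the same experiment share one
    profile; a different experiment is modelled by :meth:`DamageProfile.perturb`.
    """
    hot_probs = dict(DEFAULT_HOT_PROBS if hot_probs is None else hot_probs)
    rng = np.random.default_rng(seed)
    rates: dict[tuple[str, int, int], float] = {}
    for probe in panel:
        codes = probe.codes
        for off in range(1, probe.length - 1):  # interior: context defined
            ref = probe.region_seq[off]
            for alt_code in range(4):
                if alt_code == codes[off]:
                    continue
                alt = _seq.BASES[alt_code]
                cls = collapse_substitution(ref, alt)
                p_hot = hot_probs[cls]
                if cls == "C>T":
                    context = probe.region_seq[off - 1 : off + 2]
                    ctx, _ = collapse_context(context, alt)
                    if ctx[2] == "G":  # CpG site
                        p_hot = cpg_ct_hot_prob
                if rng.random() < p_hot:
                    rates[(probe.probe_id, off, alt_code)] = rng.lognormal(
                        math.log(hot_rate_median), hot_rate_sigma
                    )
    return DamageProfile(rates)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sample.

    Defaults are paper-scale: ~30,000 captures per probed region at ~30X
    read coverage per capture, 29 PCR cycles, 12-base UMIs.
    """

    seed: int = 0
    captures_per_probe: int = 30_000
    reads_per_capture_mean: float = 30.0
    pcr_cycles: int = 29
    pcr_error_rate: float = 3e-6
    seq_error_rate: float = 1e-3
    ct_bias: float = 8.0
    variant_spec: tuple[VariantSpec, ...] = ()
    damage_profile: DamageProfile | None = None
    first_round_errors: int = 0
    pool_cap: int = 512

    def __post_init__(self) -> None:
        for name in ("pcr_error_rate", "seq_error_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name}={rate} outside [0, 1]")
        if self.captures_per_probe < 1:
            raise ConfigError("captures_per_probe must be >= 1")
        if self.reads_per_capture_mean <= 0:
            raise ConfigError("reads_per_capture_mean must be positive")
        if self.ct_bias < 1.0:
            raise ConfigError("ct_bias must be >= 1")
        if self.pool_cap < 2:
            raise ConfigError("pool_cap must be >= 2")
        if isinstance(self.variant_spec, list):
            object.__setattr__(self, "variant_spec", tuple(self.variant_spec))


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class SimTruth:
    """Ground truth for one simulated sample.

    ``captures``: one row per capture (UMIs, haplotype, read count).
    ``template_events``: endogenous variants (round 0) and template
    damage / founding synthesis errors (round 1) -- present in ~100% of
    the capture's reads.  ``pcr_events``: exponential-cycle errors
    (round >= 2) with their final pool fraction.  ``read_events``: per
    read, the PCR-lineage and sequencing errors it carries.
    """

    captures: pd.DataFrame
    template_events: pd.DataFrame
    pcr_events: pd.DataFrame
    read_events: pd.DataFrame
    read_capture: pd.DataFrame

    def carrier_captures(self, chrom: str, pos: int, alt: str) -> int:
        """Number of captures whose template carries chrom:pos ref>alt."""
        ev = self.template_events
        mask = (ev["chrom"] == chrom) & (ev["pos"] == pos) & (ev["alt"] == alt)
        return int(ev.loc[mask, ["probe_id", "capture"]].drop_duplicates().shape[0])

    def write_tsv(self, prefix) -> None:
        for name in ("captures", "template_events", "pcr_events",
                     "read_events", "read_capture"):
            getattr(self, name).to_csv(f"{prefix}.{name}.tsv", sep="\t", index=False)


@dataclass
class ProbeMolecules:
    """Captured single-stranded molecules for one probe."""

    probe: Probe
    templates: np.ndarray  # (n_captures, L) codes, damage applied
    haplotype: np.ndarray  # (n_captures,) 0 = A, 1 = B
    umi5: np.ndarray  # (n_captures, umi_len)
    umi3: np.ndarray

    @property
    def n_captures(self) -> int:
        return self.templates.shape[0]


@dataclass
class ProbePool:
    """Amplified strand pool for one probe.

    Wild-type (= founder template) strands are implicit: every capture
    holds ``n_final`` strands of which the listed error lineages account
    for ``lineage_counts``.
    """

    molecules: ProbeMolecules
    n_final: int
    lineage_capture: np.ndarray  # (n_lineages,)
    lineage_count: np.ndarray  # (n_lineages,)
    lineage_round: np.ndarray  # (n_lineages,) cycle of origin (>= 2)
    lineage_muts: list[tuple[tuple[int, int, int], ...]]  # ((off, ref, alt), ...)

    def lineage_fraction(self, index: int) -> float:
        return float(self.lineage_count[index]) / self.n_final


@dataclass
class ProbeReads:
    probe: Probe
    r1: np.ndarray  # (n_reads, read_len) codes
    r2: np.ndarray
    capture_of_read: np.ndarray  # (n_reads,)


@dataclass
class SimResult:
    """Everything the simulator produced for one sample."""

    panel: ProbePanel
    config: SimConfig
    reads: list[ProbeReads]
    truth: SimTruth

    def read_batches(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """In-memory paired-read batches for the consensus stage."""
        return [(pr.r1, pr.r2) for pr in self.reads]

    @property
    def total_read_pairs(self) -> int:
        return sum(pr.r1.shape[0] for pr in self.reads)

    def write_fastq(self, r1_path, r2_path) -> None:
        """Write standard 4-line FASTQ (gzip if the path ends in .gz)."""
        quality = None
        handles = []
        try:
            for path in (r1_path, r2_path):
                opener = gzip.open if str(path).endswith(".gz") else open
                handles.append(opener(path, "wt"))
            serial = 0
            for pr in self.reads:
                width = pr.r1.shape[1]
                quality = "I" * width
                for mate, handle in zip((pr.r1, pr.r2), handles):
                    lines = []
                    seqs = _seq.decode_rows(mate)
                    for i, seq in enumerate(seqs):
                        lines.append(
                            f"@sim:{pr.probe.probe_id}:{serial + i}\n{seq}\n+\n{quality}\n"
                        )
                    handle.write("".join(lines))
                serial += pr.r1.shape[0]
        finally:
            for handle in handles:
                handle.close()


# ---------------------------------------------------------------------------
# closed-form anchors


def expected_het_vaf(n_founder_cells: int) -> float:
    """Expected VAF of a heterozygous mutation after an n-cell bottleneck.

    One mutant allele among 2n founder alleles: 1 / (2 n).
    """
    if n_founder_cells < 1:
        raise ConfigError("n_founder_cells must be >= 1")
    return 1.0 / (2.0 * n_founder_cells)


def divisions_to_reach(n_cells: int) -> int:
    """Cell divisions needed to grow a single cell into ``n_cells``."""
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    return math.ceil(math.log2(n_cells))


def mean_capture_coverage(total_reads: float, total_captures: float) -> float:
    """Average sequencing reads available per unique capture."""
    if total_captures <= 0:
        raise ConfigError("total_captures must be positive")
    return total_reads / total_captures


def expected_error_read_fraction(round_index: int) -> float:
    """Expected fraction of a capture's reads carrying a round-k error.

    Round 1 is the founding synthesis: its errors are inherited by the
    entire pool.  An error in exponential cycle k >= 2 arises on one of
    2**(k-1) copies made from a duplex founder and thereafter doubles
    with the pool, ending at 2**-k of the strands (25% for round 2).
    """
    if round_index < 1:
        raise ConfigError("round_index must be >= 1")
    if round_index == 1:
        return 1.0
    return 2.0 ** (-round_index)


# ---------------------------------------------------------------------------
# substitution machinery


def _choose_alts(rng: np.random.Generator, from_bases: np.ndarray,
                 ct_bias: float) -> np.ndarray:
    """Pick substitution targets; C->T and G->A weighted by ``ct_bias``."""
    n = from_bases.shape[0]
    alts = np.empty(n, dtype=np.uint8)
    u = rng.random(n)
    for base in range(4):
        mask = from_bases == base
        if not mask.any():
            continue
        others = np.array([b for b in range(4) if b != base], dtype=np.uint8)
        weights = np.ones(3)
        if base == C:
            weights[others == T] = ct_bias
        elif base == G:
            weights[others == A] = ct_bias
        weights /= weights.sum()
        edges = np.cumsum(weights)
        alts[mask] = others[np.searchsorted(edges, u[mask], side="right").clip(0, 2)]
    return alts


# ---------------------------------------------------------------------------
# stage 1: molecules


def simulate_molecules(
    panel: ProbePanel, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProbeMolecules], list[dict]]:
    """Draw captured molecules (diploid templates + damage) for every probe.

    Returns the per-probe molecule sets and the template-event truth rows
    accumulated so far (endogenous variants round 0, damage round 1).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    specs_by_probe: dict[str, list[tuple[VariantSpec, int]]] = {}
    for spec in config.variant_spec:
        hit = panel.locate(spec.chrom, spec.pos)
        if hit is None:
            raise SimSpecError(f"variant {spec.chrom}:{spec.pos} outside panel")
        probe, off = hit
        if probe.region_seq[off] != spec.ref:
            raise SimSpecError(
                f"variant {spec.chrom}:{spec.pos} ref {spec.ref!r} does not match "
                f"panel base {probe.region_seq[off]!r}"
            )
        if spec.alt not in "ACGT" or spec.alt == spec.ref:
            raise SimSpecError(f"variant {spec.chrom}:{spec.pos}: bad alt {spec.alt!r}")
        specs_by_probe.setdefault(probe.probe_id, []).append((spec, off))

    molecules = []
    events: list[dict] = []
    for probe in panel:
        n = config.captures_per_probe
        hap = rng.integers(0, 2, n).astype(np.int8)
        # somatic carriers are pinned to their haplotype
        carrier_sets: list[tuple[VariantSpec, int, np.ndarray]] = []
        for spec, off in specs_by_probe.get(probe.probe_id, []):
            hap_code = 0 if spec.haplotype == "A" else 1
            if spec.germline:
                carriers = np.flatnonzero(hap == hap_code)
            else:
                k = rng.binomial(n, spec.vaf)
                carriers = rng.choice(n, size=k, replace=False)
                hap[carriers] = hap_code
            carrier_sets.append((spec, off, carriers))
        templates = np.tile(probe.codes, (n, 1))
        for spec, off, carriers in carrier_sets:
            templates[carriers, off] = _seq.encode(spec.alt)[0]
            for cap in carriers:
                events.append(
                    {
                        "probe_id": probe.probe_id,
                        "capture": int(cap),
                        "round": 0,
                        "source": "endogenous",
                        "chrom": spec.chrom,
                        "pos": spec.pos,
                        "ref": spec.ref,
                        "alt": spec.alt,
                    }
                )
        # position-specific template damage
        if config.damage_profile is not None:
            for (probe_id, off, alt_code), rate in sorted(
                config.damage_profile.rates.items()
            ):
                if probe_id != probe.probe_id or rate <= 0:
                    continue
                hits = np.flatnonzero(rng.random(n) < rate)
                if hits.size == 0:
                    continue
                ref = probe.region_seq[off]
                alt = _seq.BASES[alt_code]
                templates[hits, off] = alt_code
                for cap in hits:
                    events.append(
                        {
                            "probe_id": probe.probe_id,
                            "capture": int(cap),
                            "round": 1,
                            "source": "damage",
                            "chrom": probe.chrom,
                            "pos": probe.start + off,
                            "ref": ref,
                            "alt": alt,
                        }
                    )
        umi5 = rng.integers(0, 4, (n, probe.umi_len)).astype(np.uint8)
        umi3 = rng.integers(0, 4, (n, probe.umi_len)).astype(np.uint8)
        molecules.append(ProbeMolecules(probe, templates, hap, umi5, umi3))
    return molecules, events


# ---------------------------------------------------------------------------
# stage 2: PCR


def simulate_pcr(
    molecules: list[ProbeMolecules],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    template_events: list[dict] | None = None,
    forced_errors: list[tuple[str, int, int, int, int]] | None = None,
) -> tuple[list[ProbePool], list[dict]]:
    """Amplify each capture with a capped branching doubling process.

    ``forced_errors`` entries are (probe_id, capture, cycle, offset,
    alt_code) and inject one deterministic error on one copy made in that
    cycle (cycle 1 = founding synthesis), for controlled experiments.

    Returns per-probe pools plus the template-event rows for round-1
    errors (founding synthesis); cycle >= 2 errors live in the pools'
    lineage tables.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    template_events = [] if template_events is None else template_events
    forced = forced_errors or []
    if config.first_round_errors and molecules:
        r1_allocation = rng.multinomial(
            config.first_round_errors,
            np.full(len(molecules), 1.0 / len(molecules)),
        )
    else:
        r1_allocation = np.zeros(len(molecules), dtype=np.int64)
    pools = []
    for probe_index, mol in enumerate(molecules):
        probe = mol.probe
        n_caps = mol.n_captures
        L = probe.length
        # --- round 1: founding synthesis errors hit the whole capture
        r1_caps: list[int] = []
        r1_offs: list[int] = []
        n_r1 = rng.binomial(n_caps * L, config.pcr_error_rate)
        if n_r1:
            r1_caps.extend(rng.integers(0, n_caps, n_r1).tolist())
            r1_offs.extend(rng.integers(0, L, n_r1).tolist())
        n_forced_r1 = int(r1_allocation[probe_index])
        if n_forced_r1:
            r1_caps.extend(rng.integers(0, n_caps, n_forced_r1).tolist())
            r1_offs.extend(rng.integers(0, L, n_forced_r1).tolist())
        for probe_id, cap, cycle, off, alt_code in forced:
            if probe_id == probe.probe_id and cycle == 1:
                ref = _seq.BASES[mol.templates[cap, off]]
                mol.templates[cap, off] = alt_code
                template_events.append(
                    {
                        "probe_id": probe.probe_id,
                        "capture": int(cap),
                        "round": 1,
                        "source": "first_round",
                        "chrom": probe.chrom,
                        "pos": probe.start + off,
                        "ref": ref,
                        "alt": _seq.BASES[alt_code],
                    }
                )
        if r1_caps:
            caps_arr = np.array(r1_caps)
            offs_arr = np.array(r1_offs)
            from_bases = mol.templates[caps_arr, offs_arr]
            valid = from_bases < 4
            caps_arr, offs_arr, from_bases = (
                caps_arr[valid], offs_arr[valid], from_bases[valid]
            )
            alts = _choose_alts(rng, from_bases, config.ct_bias)
            mol.templates[caps_arr, offs_arr] = alts
            for cap, off, fb, tb in zip(caps_arr, offs_arr, from_bases, alts):
                template_events.append(
                    {
                        "probe_id": probe.probe_id,
                        "capture": int(cap),
                        "round": 1,
                        "source": "first_round",
                        "chrom": probe.chrom,
                        "pos": probe.start + int(off),
                        "ref": _seq.BASES[fb],
                        "alt": _seq.BASES[tb],
                    }
                )

        # --- cycles 2..pcr_cycles: duplex founder doubles each cycle
        lin_cap: np.ndarray = np.empty(0, dtype=np.int64)
        lin_count: np.ndarray = np.empty(0, dtype=np.int64)
        lin_round: np.ndarray = np.empty(0, dtype=np.int64)
        lin_muts: list[tuple[tuple[int, int, int], ...]] = []
        n_prev = 2
        for cycle in range(2, config.pcr_cycles + 1):
            prev_counts = lin_count.copy()
            lin_count = lin_count * 2
            new_cap: list[int] = []
            new_round: list[int] = []
            new_muts: list[tuple[tuple[int, int, int], ...]] = []
            n_err = rng.binomial(n_caps * n_prev * L, config.pcr_error_rate)
            if n_err:
                err_caps = rng.integers(0, n_caps, n_err)
                err_offs = rng.integers(0, L, n_err)
                # does the erroneous copy descend from an existing lineage?
                if lin_cap.size:
                    mass_prev = np.bincount(lin_cap, prev_counts, minlength=n_caps)
                else:
                    mass_prev = np.zeros(n_caps)
                on_lineage = rng.random(n_err) * n_prev < mass_prev[err_caps]
                from_bases = mol.templates[err_caps, err_offs]
                alts = _choose_alts(rng, from_bases, config.ct_bias)
                for i in range(n_err):
                    cap, off = int(err_caps[i]), int(err_offs[i])
                    parent_muts: tuple[tuple[int, int, int], ...] = ()
                    if on_lineage[i]:
                        members = np.flatnonzero(lin_cap == cap)
                        weights = prev_counts[members].astype(float)
                        if weights.sum() > 0:
                            j = int(rng.choice(members, p=weights / weights.sum()))
                            lin_count[j] -= 1
                            parent_muts = lin_muts[j]
                    ref = int(from_bases[i])
                    for m_off, _, m_alt in parent_muts:
                        if m_off == off:
                            ref = m_alt
                    alt = int(alts[i])
                    if alt == ref:  # nested error reverted the base; re-pick
                        alt = (ref + 1) % 4
                    new_cap.append(cap)
                    new_round.append(cycle)
                    new_muts.append(parent_muts + ((off, ref, alt),))
            for probe_id, cap, f_cycle, off, alt_code in forced:
                if probe_id == probe.probe_id and f_cycle == cycle:
                    ref = int(mol.templates[cap, off])
                    new_cap.append(int(cap))
                    new_round.append(cycle)
                    new_muts.append(((int(off), ref, int(alt_code)),))
            if new_cap:
                lin_cap = np.concatenate([lin_cap, np.array(new_cap, dtype=np.int64)])
                lin_count = np.concatenate(
                    [lin_count, np.ones(len(new_cap), dtype=np.int64)]
                )
                lin_round = np.concatenate(
                    [lin_round, np.array(new_round, dtype=np.int64)]
                )
                lin_muts.extend(new_muts)
            n_now = 2 * n_prev
            if n_now > config.pool_cap:
                if lin_count.size:
                    lin_count = rng.hypergeometric(
                        lin_count, n_now - lin_count, config.pool_cap
                    )
                    # rare joint overdraw: trim proportionally
                    mass = np.bincount(lin_cap, lin_count, minlength=n_caps)
                    over = np.flatnonzero(mass > config.pool_cap)
                    for cap in over:
                        members = np.flatnonzero(lin_cap == cap)
                        excess = int(mass[cap]) - config.pool_cap
                        for j in members[np.argsort(-lin_count[members])]:
                            take = min(excess, int(lin_count[j]))
                            lin_count[j] -= take
                            excess -= take
                            if excess == 0:
                                break
                n_now = config.pool_cap
            n_prev = n_now
            if lin_count.size and (lin_count == 0).any():
                keep = lin_count > 0
                lin_cap, lin_count, lin_round = (
                    lin_cap[keep], lin_count[keep], lin_round[keep]
                )
                lin_muts = [m for m, k in zip(lin_muts, keep) if k]
        pools.append(
            ProbePool(mol, n_prev, lin_cap, lin_count, lin_round, lin_muts)
        )
    return pools, template_events


# ---------------------------------------------------------------------------
# stage 3: reads


def simulate_reads(
    pools: list[ProbePool],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ProbeReads], pd.DataFrame, pd.DataFrame, list[dict]]:
    """Sample strands into fully overlapping read pairs with sequencing noise.

    Returns the per-probe reads, the per-read event table (PCR-lineage and
    sequencing errors attributed to individual reads), the read->capture
    map, and the capture summary table.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    all_reads = []
    read_event_rows: list[dict] = []
    read_event_frames: list[pd.DataFrame] = []
    read_capture_rows = []
    capture_rows = []
    for pool in pools:
        mol = pool.molecules
        probe = mol.probe
        L = probe.length
        umi = probe.umi_len
        n_caps = mol.n_captures
        r_c = rng.poisson(config.reads_per_capture_mean, n_caps)
        total = int(r_c.sum())
        capture_of_read = np.repeat(np.arange(n_caps), r_c)
        read_start = np.zeros(n_caps + 1, dtype=np.int64)
        np.cumsum(r_c, out=read_start[1:])
        inserts = mol.templates[capture_of_read]
        # distribute PCR-lineage errors onto reads
        if pool.lineage_count.size:
            k_per_lineage = rng.binomial(
                r_c[pool.lineage_capture],
                pool.lineage_count / pool.n_final,
            )
            for j in np.flatnonzero(k_per_lineage):
                cap = int(pool.lineage_capture[j])
                k = int(k_per_lineage[j])
                rows = read_start[cap] + rng.choice(int(r_c[cap]), k, replace=False)
                for off, ref, alt in pool.lineage_muts[j]:
                    inserts[rows, off] = alt
                    for row in rows:
                        read_event_rows.append(
                            {
                                "probe_id": probe.probe_id,
                                "read_index": int(row),
                                "mate": 0,
                                "source": "pcr",
                                "round": int(pool.lineage_round[j]),
                                "chrom": probe.chrom,
                                "pos": probe.start + off,
                                "ref": _seq.BASES[ref],
                                "alt": _seq.BASES[alt],
                            }
                        )
        amplicon = np.concatenate(
            [mol.umi5[capture_of_read], inserts, mol.umi3[capture_of_read]], axis=1
        )
        r1 = amplicon
        r2 = _seq.revcomp(amplicon)
        width = L + 2 * umi
        base_labels = np.array(list(_seq.BASES))
        for mate_index, mate in enumerate((r1, r2)):
            n_e = rng.binomial(total * width, config.seq_error_rate)
            if n_e == 0:
                continue
            rows = rng.integers(0, total, n_e)
            cols = rng.integers(0, width, n_e)
            from_bases = mate[rows, cols]
            alts = ((from_bases + rng.integers(1, 4, n_e)) % 4).astype(np.uint8)
            mate[rows, cols] = alts
            if mate_index == 0:
                amp_cols = cols
                plus_ref, plus_alt = from_bases, alts
            else:
                amp_cols = width - 1 - cols
                plus_ref = _seq.COMPLEMENT[from_bases]
                plus_alt = _seq.COMPLEMENT[alts]
            inside = (amp_cols >= umi) & (amp_cols < umi + L)
            read_event_frames.append(
                pd.DataFrame(
                    {
                        "probe_id": probe.probe_id,
                        "read_index": rows,
                        "mate": mate_index + 1,
                        "source": "sequencing",
                        "round": -1,
                        "chrom": np.where(inside, probe.chrom, "."),
                        "pos": np.where(inside, probe.start + (amp_cols - umi), -1),
                        "ref": base_labels[plus_ref],
                        "alt": base_labels[plus_alt],
                    }
                )
            )
        all_reads.append(ProbeReads(probe, r1, r2, capture_of_read))
        read_capture_rows.append(
            pd.DataFrame(
                {
                    "probe_id": probe.probe_id,
                    "read_index": np.arange(total),
                    "capture": capture_of_read,
                }
            )
        )
        capture_rows.append(
            pd.DataFrame(
                {
                    "probe_id": probe.probe_id,
                    "capture": np.arange(n_caps),
                    "umi5": _seq.decode_rows(mol.umi5),
                    "umi3": _seq.decode_rows(mol.umi3),
                    "haplotype": np.where(mol.haplotype == 0, "A", "B"),
                    "n_reads": r_c,
                }
            )
        )
    event_columns = ["probe_id", "read_index", "mate", "source", "round",
                     "chrom", "pos", "ref", "alt"]
    frames = [pd.DataFrame(read_event_rows, columns=event_columns)]
    frames.extend(read_event_frames)
    read_events = pd.concat(
        [f for f in frames if not f.empty], ignore_index=True
    ) if any(not f.empty for f in frames) else frames[0]
    read_capture = (
        pd.concat(read_capture_rows, ignore_index=True)
        if read_capture_rows
        else pd.DataFrame(columns=["probe_id", "read_index", "capture"])
    )
    captures = pd.concat(capture_rows, ignore_index=True)
    return all_reads, read_events, read_capture, captures


# ---------------------------------------------------------------------------
# orchestration


_EVENT_COLUMNS = ["probe_id", "capture", "round", "source", "chrom", "pos", "ref", "alt"]


def simulate_library(
    panel: ProbePanel,
    config: SimConfig,
    forced_errors: list[tuple[str, int, int, int, int]] | None = None,
) -> SimResult:
    """Run the full molecule -> PCR -> reads stack for one sample.

    Fully deterministic for a fixed ``config.seed`` (byte-identical FASTQ).
    """
    rng = np.random.default_rng(config.seed)
    molecules, template_events = simulate_molecules(panel, config, rng)
    pools, template_events = simulate_pcr(
        molecules, config, rng, template_events, forced_errors
    )
    reads, read_events, read_capture, capture_table = simulate_reads(
        pools, config, rng
    )
    pcr_rows = []
    for pool in pools:
        for j in range(pool.lineage_count.size):
            for off, ref, alt in pool.lineage_muts[j]:
                pcr_rows.append(
                    {
                        "probe_id": pool.molecules.probe.probe_id,
                        "capture": int(pool.lineage_capture[j]),
                        "round": int(pool.lineage_round[j]),
                        "chrom": pool.molecules.probe.chrom,
                        "pos": pool.molecules.probe.start + off,
                        "ref": _seq.BASES[ref],
                        "alt": _seq.BASES[alt],
                        "pool_fraction": pool.lineage_fraction(j),
                    }
                )
    truth = SimTruth(
        captures=capture_table,
        template_events=pd.DataFrame(template_events, columns=_EVENT_COLUMNS),
        pcr_events=pd.DataFrame(
            pcr_rows, columns=_EVENT_COLUMNS + ["pool_fraction"]
        ),
        read_events=read_events,
        read_capture=read_capture,
    )
    return SimResult(panel, config, reads, truth)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of a config with a different seed (controls of one experiment)."""
    return replace(config, seed=seed)
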