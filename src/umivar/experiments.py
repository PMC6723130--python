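"""Canned validation studies run entirely on simulated libraries.

Each function reproduces one of the assay's standard bench experiments
at desk scale: spiking a variant at the 1/10,000 detection limit against
an internal background, flooding a library with first-round PCR errors,
and recovering a dilution series.  They are used by the test suite and
by ``scripts/acceptance.py``; problem sizes default to values a single
CPU handles in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from .background import (
    BackgroundModel,
    SubKey,
    alpha_from_nines,
    build_generic_background,
    build_position_background,
    filter_variants,
)
from .callvars import PanelIndex, align_consensus, build_pileup, call_variants
from .consensus import ConsensusSet, run_consensus
from .contexts import collapse_substitution
from .panel import Probe, ProbePanel
from .simulate import (
    DamageProfile,
    SimConfig,
    SimResult,
    VariantSpec,
    make_damage_profile,
    simulate_library,
)


def derive_seed(seed: int, stream: int) -> int:
    """Deterministic child seed, kept below 2**31."""
    return (seed * 7919 + stream * 104_729 + 1) % (2**31)


def synthetic_panel(
    n_probes: int = 32,
    region_length: int = 126,
    seed: int = 101,
    chrom: str = "chr1",
) -> ProbePanel:
    """Random GC-balanced panel; 126 bp regions give 150 bp reads with
    two 12-base UMIs, the standard paired-end 150 layout."""
    rng = np.random.default_rng(seed)
    probes = []
    start = 10_000
    for i in range(n_probes):
        seq = _seq.decode(rng.integers(0, 4, region_length).astype(np.uint8))
        probes.append(
            Probe(
                probe_id=f"probe{i + 1:02d}",
                chrom=chrom,
                start=start,
                end=start + region_length - 1,
                strand="+" if i % 2 == 0 else "-",
                region_seq=seq,
            )
        )
        start += region_length + 10_000
    return ProbePanel(probes, genome_label="synthetic")


def clean_assay_site(
    panel: ProbePanel,
    profile: DamageProfile,
    prefer_class: str = "T>G",
    alt_for_ref: dict[str, str] | None = None,
) -> SubKey:
    """Pick a damage-free interior site for a spike-in, the way a bench
    scientist picks a known-clean locus for a dilution series.

    Prefers substitutions of ``prefer_class`` (rarely a damage hotspot);
    scans from the centre of the first probe outward and returns the
    first (position, alt) with zero damage rate.
    """
    alt_for_ref = alt_for_ref or {"T": "G", "A": "C", "C": "A", "G": "T"}
    for probe in panel:
        centre = probe.length // 2
        order = sorted(range(1, probe.length - 1), key=lambda o: abs(o - centre))
        for off in order:
            ref = probe.region_seq[off]
            alt = alt_for_ref[ref]
            if collapse_substitution(ref, alt) != prefer_class:
                continue
            if (probe.probe_id, off, int(_seq.encode(alt)[0])) in profile.rates:
                continue
            return SubKey(probe.chrom, probe.start + off, ref, alt)
    raise LookupError("no damage-free site of the preferred class in this panel")


@dataclass
class SampleRun:
    """One simulated sample pushed through the full calling stack."""

    sim: SimResult
    consensus: ConsensusSet
    calls: pd.DataFrame


def run_sample(
    panel: ProbePanel,
    config: SimConfig,
    index: PanelIndex | None = None,
    min_reads: int = 5,
    agreement: float = 0.75,
    barcode_mismatch: int = 1,
    min_capture_support: int = 5,
) -> SampleRun:
    """simulate -> merge/cluster/collapse -> align -> pileup -> call."""
    if index is None:
        index = PanelIndex(panel)
    sim = simulate_library(panel, config)
    umi_len = panel.probes[0].umi_len
    consensus = run_consensus(
        sim.read_batches(),
        umi_len=umi_len,
        min_reads=min_reads,
        agreement=agreement,
        max_mismatch=barcode_mismatch,
    )
    aligned = align_consensus(consensus, panel, index=index)
    calls = call_variants(build_pileup(aligned, panel), panel, min_capture_support)
    return SampleRun(sim=sim, consensus=consensus, calls=calls)


# ---------------------------------------------------------------------------
# spike at the detection limit


@dataclass
class SpikeDetectionResult:
    panel: ProbePanel
    spike: SubKey
    het: SubKey
    model: BackgroundModel
    control_calls: list[pd.DataFrame] = field(default_factory=list)
    test_calls: pd.DataFrame | None = None
    flagged: pd.DataFrame | None = None
    carrier_captures: int = 0
    detected: bool = False
    observed_vaf: float = 0.0
    het_vaf: float = 0.0
    het_significant: bool = False


def spike_detection_experiment(
    seed: int,
    spike_vaf: float = 1e-4,
    captures_test: int = 50_000,
    n_controls: int = 10,
    captures_control: int = 50_000,
    reads_per_capture_mean: float = 10.0,
    alpha_nines: int = 10,
    pcr_cycles: int = 29,
) -> SpikeDetectionResult:
    """Spike a somatic variant at the 1/10,000 limit and call it against
    an internal background built from co-run control samples.

    All samples share one panel and one damage landscape (same
    experiment); controls differ only in sampling noise and are captured
    at the same depth as the test sample, so the positional background
    sees every hotspot the test sample can reach.  The spike site is a
    damage-free T>G locus, the clean-site condition under which the
    1/10,000 limit holds (at hot positions the background itself sits
    above that VAF and detection is impossible by construction).
    """
    panel = synthetic_panel(n_probes=1, seed=derive_seed(seed, 1))
    profile = make_damage_profile(panel, seed=derive_seed(seed, 2))
    spike = clean_assay_site(panel, profile, prefer_class="T>G")
    het = clean_assay_site(
        panel, profile, prefer_class="T>C", alt_for_ref={"T": "C", "A": "G",
                                                         "C": "T", "G": "A"}
    )
    het_spec = VariantSpec(het.chrom, het.pos, het.ref, het.alt, 0.5,
                           haplotype="A", germline=True)
    index = PanelIndex(panel)
    alpha = alpha_from_nines(alpha_nines)

    control_calls = []
    for i in range(n_controls):
        config = SimConfig(
            seed=derive_seed(seed, 10 + i),
            captures_per_probe=captures_control,
            reads_per_capture_mean=reads_per_capture_mean,
            pcr_cycles=pcr_cycles,
            damage_profile=profile,
            variant_spec=(het_spec,),
        )
        control_calls.append(run_sample(panel, config, index).calls)
    model = build_position_background(
        control_calls, panel, alpha=alpha, outlier_drop=1, kind="internal"
    )

    spike_spec = VariantSpec(spike.chrom, spike.pos, spike.ref, spike.alt,
                             spike_vaf, haplotype="A")
    test_config = SimConfig(
        seed=derive_seed(seed, 99),
        captures_per_probe=captures_test,
        reads_per_capture_mean=reads_per_capture_mean,
        pcr_cycles=pcr_cycles,
        damage_profile=profile,
        variant_spec=(het_spec, spike_spec),
    )
    test = run_sample(panel, test_config, index)
    flagged = filter_variants(test.calls, model, alpha, panel)

    result = SpikeDetectionResult(
        panel=panel, spike=spike, het=het, model=model,
        control_calls=control_calls, test_calls=test.calls, flagged=flagged,
        carrier_captures=test.sim.truth.carrier_captures(
            spike.chrom, spike.pos, spike.alt
        ),
    )
    spike_rows = flagged[
        (flagged["pos"] == spike.pos) & (flagged["alt"] == spike.alt)
    ]
    if len(spike_rows):
        result.observed_vaf = float(spike_rows["vaf"].iloc[0])
        result.detected = bool(spike_rows["significant"].iloc[0])
    het_rows = flagged[(flagged["pos"] == het.pos) & (flagged["alt"] == het.alt)]
    if len(het_rows):
        result.het_vaf = float(het_rows["vaf"].iloc[0])
        result.het_significant = bool(het_rows["significant"].iloc[0])
    return result


def positional_vs_generic(
    result: SpikeDetectionResult, alpha: float = 0.99
) -> dict:
    """False/true positive counts under positional vs generic filtering.

    True signal is the spiked variant and the germline het; everything
    else flagged significant is a false positive.  Position-specific
    backgrounds should never do worse than the context-only fallback.
    """
    panel = result.panel
    generic_model = build_generic_background(
        result.control_calls, panel, alpha=result.model.alpha
    )
    truth_keys = {(result.spike.pos, result.spike.alt), (result.het.pos, result.het.alt)}
    out = {}
    for label, model in (("positional", result.model), ("generic", generic_model)):
        flagged = filter_variants(result.test_calls, model, alpha, panel)
        hits = flagged[flagged["significant"]]
        keys = set(zip(hits["pos"], hits["alt"]))
        out[f"{label}_false_positives"] = len(keys - truth_keys)
        out[f"{label}_true_positives"] = len(keys & truth_keys)
    return out


# ---------------------------------------------------------------------------
# first-round PCR errors vs the multi-capture rule


@dataclass
class FirstRoundErrorResult:
    n_errors: int
    n_in_consensus: int
    n_surviving_calls: int
    calls: pd.DataFrame


def first_round_error_experiment(
    seed: int,
    n_probes: int = 32,
    captures_per_probe: int = 940,
    n_errors: int = 400,
    reads_per_capture_mean: float = 10.0,
    min_capture_support: int = 5,
) -> FirstRoundErrorResult:
    """Inject independent first-round PCR errors and count survivors.

    Each error converts a single capture, so it sails through paired-end
    merging and UMI collapsing; only the requirement that a variant be
    seen in >= ``min_capture_support`` independent captures removes it.
    With ~400 errors spread over ~12,000 possible substitutions the
    chance of five collisions at one key is negligible, so zero survivors
    is the expected outcome.  All other error channels are off.
    """
    panel = synthetic_panel(n_probes=n_probes, seed=derive_seed(seed, 3))
    config = SimConfig(
        seed=derive_seed(seed, 4),
        captures_per_probe=captures_per_probe,
        reads_per_capture_mean=reads_per_capture_mean,
        pcr_error_rate=0.0,
        seq_error_rate=0.0,
        first_round_errors=n_errors,
    )
    run = run_sample(panel, config, min_capture_support=min_capture_support)
    events = run.sim.truth.template_events
    errors = events[events["round"] == 1]
    call_keys = set(
        zip(run.calls["chrom"], run.calls["pos"], run.calls["alt"])
    )
    surviving = sum(
        1
        for row in errors.itertuples(index=False)
        if (row.chrom, row.pos, row.alt) in call_keys
    )
    # how many reached a consensus read at all (capture-level survival)
    aligned = align_consensus(run.consensus, panel)
    pileup = build_pileup(aligned, panel)
    n_in_consensus = 0
    for row in errors.itertuples(index=False):
        probe, off = panel.locate(row.chrom, int(row.pos))
        alt_code = int(_seq.encode(row.alt)[0])
        if pileup.counts[probe.probe_id][off, alt_code] >= 1:
            n_in_consensus += 1
    return FirstRoundErrorResult(
        n_errors=int(len(errors)),
        n_in_consensus=n_in_consensus,
        n_surviving_calls=surviving,
        calls=run.calls,
    )


# ---------------------------------------------------------------------------
# dilution series


def dilution_experiment(
    seed: int,
    dilutions: tuple[float, ...] = (1.0, 0.1, 0.01, 2e-3, 2e-4),
    captures: tuple[int, ...] = (8_000, 8_000, 8_000, 20_000, 50_000),
    n_controls: int = 6,
    captures_control: int = 12_000,
    reads_per_capture_mean: float = 10.0,
    alpha_nines: int = 6,
) -> tuple[pd.DataFrame, SubKey]:
    """Serially dilute a heterozygous variant and measure recovery.

    A dilution d of a het carrier means a fraction d of captured alleles
    come from the carrier, so the expected VAF is d/2.  Capture depth per
    point scales with the expected VAF so the rarest point retains ~5
    expected carrier captures, mirroring how sequencing effort is
    allocated on the bench.
    """
    from .analyses import evaluate_dilution

    panel = synthetic_panel(n_probes=1, seed=derive_seed(seed, 5))
    profile = make_damage_profile(panel, seed=derive_seed(seed, 6))
    site = clean_assay_site(panel, profile, prefer_class="T>G")
    index = PanelIndex(panel)
    alpha = alpha_from_nines(alpha_nines)

    control_calls = []
    for i in range(n_controls):
        config = SimConfig(
            seed=derive_seed(seed, 50 + i),
            captures_per_probe=captures_control,
            reads_per_capture_mean=reads_per_capture_mean,
            damage_profile=profile,
        )
        control_calls.append(run_sample(panel, config, index).calls)
    model = build_position_background(
        control_calls, panel, alpha=alpha, outlier_drop=1, kind="internal"
    )

    call_sets = []
    for point, (dilution, n_captures) in enumerate(zip(dilutions, captures)):
        spec = VariantSpec(site.chrom, site.pos, site.ref, site.alt,
                           dilution / 2.0, haplotype="A")
        config = SimConfig(
            seed=derive_seed(seed, 200 + point),
            captures_per_probe=n_captures,
            reads_per_capture_mean=reads_per_capture_mean,
            damage_profile=profile,
            variant_spec=(spec,),
        )
        call_sets.append(run_sample(panel, config, index).calls)
    points = evaluate_dilution(call_sets, site, list(dilutions), model, alpha)
    return points, site
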