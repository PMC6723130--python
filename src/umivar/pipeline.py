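"""End-to-end run configuration and orchestration.

`run_pipeline` wires consensus -> alignment -> calling -> background ->
filtering for a set of per-sample FASTQ pairs.  Control samples of the
same invocation feed the internal background; an external model can be
loaded from a serialized TSV instead.  Sample demultiplexing by the
16-bp sample index is assumed done upstream (per-sample FASTQs), as is
standard for Illumina output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .background import (
    BackgroundModel,
    alpha_from_nines,
    build_generic_background,
    build_position_background,
    filter_variants,
)
from .callvars import (
    PanelIndex,
    align_consensus,
    build_pileup,
    call_variants,
    read_vcf,
    write_vcf,
)
from .consensus import read_fastq_pairs, run_consensus
from .errors import ConfigError
from .panel import ProbePanel, load_panel


@dataclass
class SampleSpec:
    """One sample's inputs: FASTQ pair, or a pre-made calls VCF."""

    name: str
    r1: str | None = None
    r2: str | None = None
    vcf: str | None = None
    role: str = "test"  # test | control

    def __post_init__(self) -> None:
        if self.role not in ("test", "control"):
            raise ConfigError(f"sample {self.name}: role must be test or control")
        if self.vcf is None and (self.r1 is None or self.r2 is None):
            raise ConfigError(f"sample {self.name}: need r1+r2 or vcf")


@dataclass
class RunConfig:
    panel: str = ""
    samples: list[SampleSpec] = field(default_factory=list)
    min_reads: int = 5
    agreement: float = 0.75
    barcode_mismatch: int = 1
    min_capture_support: int = 5
    alpha_nines: int = 3
    background_mode: str = "internal"  # internal | external | generic
    background_model: str | None = None  # TSV path for external mode
    outlier_drop: int = 1
    umi_len: int = 12
    seed: int = 0
    outdir: str = "umivar_out"

    def __post_init__(self) -> None:
        if not 0.5 < self.agreement <= 1.0:
            raise ConfigError("agreement must lie in (0.5, 1]")
        for name in ("min_reads", "min_capture_support", "alpha_nines"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.background_mode not in ("internal", "external", "generic"):
            raise ConfigError("background_mode must be internal/external/generic")
        if self.background_mode == "external" and not self.background_model:
            raise ConfigError("external background mode requires background_model")
        self.samples = [
            SampleSpec(**s) if isinstance(s, dict) else s for s in self.samples
        ]

    @property
    def alpha(self) -> float:
        return alpha_from_nines(self.alpha_nines)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as handle:
            yaml.safe_dump(payload, handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle)
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: not a mapping")
        try:
            return cls(**payload)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


def _sample_calls(
    sample: SampleSpec,
    panel: ProbePanel,
    index: PanelIndex,
    config: RunConfig,
    outdir: Path,
    qc_rows: list[dict],
) -> pd.DataFrame:
    if sample.vcf is not None:
        return read_vcf(sample.vcf, panel)
    batches = read_fastq_pairs(sample.r1, sample.r2)
    consensus = run_consensus(
        batches,
        umi_len=config.umi_len,
        min_reads=config.min_reads,
        agreement=config.agreement,
        max_mismatch=config.barcode_mismatch,
    )
    consensus.write_fasta(outdir / f"{sample.name}.consensus.fasta")
    aligned = align_consensus(consensus, panel, index=index)
    pileup = build_pileup(aligned, panel)
    calls = call_variants(pileup, panel, config.min_capture_support)
    write_vcf(calls, panel, outdir / f"{sample.name}.calls.vcf")
    qc = consensus.qc.as_dict()
    qc.update(
        {
            "sample": sample.name,
            "role": sample.role,
            "aligned": aligned.n_aligned,
            "align_rejected": aligned.n_rejected,
            "raw_calls": len(calls),
        }
    )
    qc_rows.append(qc)
    return calls


def run_pipeline(config: RunConfig) -> dict:
    """Run the full stack; returns a summary dict (also written as JSON).

    Deterministic given the inputs: the pipeline itself consumes no
    randomness (``seed`` is threaded to any simulation step upstream).
    """
    panel = load_panel(config.panel, umi_len=config.umi_len)
    index = PanelIndex(panel)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")

    qc_rows: list[dict] = []
    control_calls = []
    test_calls: dict[str, pd.DataFrame] = {}
    for sample in config.samples:
        calls = _sample_calls(sample, panel, index, config, outdir, qc_rows)
        if sample.role == "control":
            control_calls.append(calls)
        else:
            test_calls[sample.name] = calls

    if config.background_mode == "external":
        model = BackgroundModel.from_tsv(config.background_model)
    elif config.background_mode == "generic":
        model = build_generic_background(control_calls, panel, config.alpha)
    else:
        model = build_position_background(
            control_calls, panel, config.alpha,
            outlier_drop=config.outlier_drop, kind="internal",
        )
    model.to_tsv(outdir / "background_model.tsv")

    summary: dict = {"samples": {}, "alpha": config.alpha,
                     "background_mode": config.background_mode}
    for name, calls in test_calls.items():
        flagged = filter_variants(calls, model, config.alpha, panel)
        significant = flagged[flagged["significant"]]
        write_vcf(flagged, panel, outdir / f"{name}.filtered.vcf")
        write_vcf(significant, panel, outdir / f"{name}.significant.vcf")
        summary["samples"][name] = {
            "raw_calls": int(len(calls)),
            "significant_calls": int(len(significant)),
        }
    if qc_rows:
        pd.DataFrame(qc_rows).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
    return summary
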