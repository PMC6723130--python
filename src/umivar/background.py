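"""Empirical error background and significance filtering.

Control samples (peripheral blood run through the same assay) define,
for every (position, substitution) at which they show a variant, an
empirical distribution of false-positive VAFs.  Each is modelled as a
Student's t with df = n - 1, location = mean and scale = sample standard
deviation of the per-control VAFs (zeros included for controls lacking
the call, top outliers dropped to keep true mutations out of the
background).  A call is significant when its VAF exceeds the high
endpoint of the central alpha confidence interval of its governing
distribution.  Substitutions never seen in controls fall back to a
generic per-(trinucleotide context, alt) background pooled across all
positions -- the positional model always takes precedence: position
beats context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigError,
    DataError,
    FilterError,
    InsufficientControlsError,
)
from .contexts import SUBSTITUTION_CLASSES, collapse_context, collapse_substitution
from .panel import ProbePanel


class SubKey(NamedTuple):
    """A specific substitution at a specific probed position."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class BackgroundDistribution:
    """Student's-t background over control VAFs for one key or class."""

    n_controls: int
    location: float
    scale: float
    low: float
    high: float
    vafs: tuple[float, ...] = ()

    @property
    def df(self) -> int:
        return self.n_controls - 1


def fit_background_distribution(
    vafs: np.ndarray, alpha: float, outlier_drop: int = 0
) -> BackgroundDistribution:
    """Fit a t background to one key's control VAF vector.

    The ``outlier_drop`` highest VAFs are removed first ("the highest
    frequency alleles were eliminated") so a real mutation present in a
    control cannot inflate the background.
    """
    vafs = np.sort(np.asarray(vafs, dtype=float))
    if outlier_drop:
        vafs = vafs[: max(len(vafs) - outlier_drop, 0)]
    if len(vafs) < 2:
        raise InsufficientControlsError(
            "need >= 2 control VAFs per key after outlier removal"
        )
    location = float(vafs.mean())
    scale = float(vafs.std(ddof=1))
    low, high = _t_interval(len(vafs) - 1, location, scale, alpha)
    return BackgroundDistribution(
        n_controls=len(vafs),
        location=location,
        scale=scale,
        low=low,
        high=high,
        vafs=tuple(float(v) for v in vafs),
    )


def _t_interval(df: int, location: float, scale: float, alpha: float) -> tuple[float, float]:
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must lie strictly in (0, 1), got {alpha}")
    if scale == 0.0:
        return location, location
    low, high = stats.t.interval(alpha, df, loc=location, scale=scale)
    return max(float(low), 0.0), float(high)


def ci_endpoints(
    dist: BackgroundDistribution, alpha: float
) -> tuple[float, float]:
    """Central alpha-mass interval of the fitted t, low floored at 0."""
    return _t_interval(dist.df, dist.location, dist.scale, alpha)


def alpha_from_nines(nines: int) -> float:
    """Alpha expressed as a count of trailing 9s: 1 -> 0.9, 3 -> 0.999 ..."""
    if nines < 1:
        raise ConfigError("nines must be >= 1")
    return 1.0 - 10.0 ** (-nines)


@dataclass
class BackgroundModel:
    """Positional t distributions plus the generic context fallback.

    ``kind`` records provenance only: an *internal* model is built from
    control samples of the same experiment, an *external* one from a
    different experiment, and a *generic* model carries no positional
    distributions at all.
    """

    kind: str
    alpha: float
    outlier_drop: int
    n_controls: int
    positional: dict[SubKey, BackgroundDistribution] = field(default_factory=dict)
    generic: dict[tuple[str, str], BackgroundDistribution] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("internal", "external", "generic"):
            raise ConfigError(f"unknown background kind {self.kind!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie strictly in (0, 1)")

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path) -> None:
        meta = {
            "kind": self.kind,
            "alpha": self.alpha,
            "outlier_drop": self.outlier_drop,
            "n_controls": self.n_controls,
        }
        rows = []
        for key, dist in sorted(self.positional.items()):
            rows.append(
                ("positional", key.chrom, key.pos, key.ref, key.alt,
                 dist.n_controls, dist.location, dist.scale, dist.low, dist.high)
            )
        for (context, alt), dist in sorted(self.generic.items()):
            rows.append(
                ("generic", context, -1, ".", alt,
                 dist.n_controls, dist.location, dist.scale, dist.low, dist.high)
            )
        table = pd.DataFrame(
            rows,
            columns=["tier", "locus", "pos", "ref", "alt",
                     "n", "location", "scale", "low", "high"],
        )
        with open(path, "w") as handle:
            handle.write("#" + json.dumps(meta) + "\n")
            table.to_csv(handle, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BackgroundModel":
        with open(path) as handle:
            first = handle.readline()
            if not first.startswith("#"):
                raise DataError(f"{path}: missing model metadata line")
            meta = json.loads(first[1:])
            table = pd.read_csv(handle, sep="\t", dtype={"locus": str})
        model = cls(
            kind=meta["kind"],
            alpha=float(meta["alpha"]),
            outlier_drop=int(meta["outlier_drop"]),
            n_controls=int(meta["n_controls"]),
        )
        for row in table.itertuples(index=False):
            dist = BackgroundDistribution(
                n_controls=int(row.n),
                location=float(row.location),
                scale=float(row.scale),
                low=float(row.low),
                high=float(row.high),
            )
            if row.tier == "positional":
                model.positional[
                    SubKey(row.locus, int(row.pos), row.ref, row.alt)
                ] = dist
            else:
                model.generic[(row.locus, row.alt)] = dist
        return model


def _control_vaf_table(
    control_call_sets: list[pd.DataFrame], het_ceiling: float | None
) -> tuple[dict[SubKey, np.ndarray], int]:
    """Per-key VAF vector across controls (0 where a control lacks the key)."""
    n = len(control_call_sets)
    if n < 2:
        raise InsufficientControlsError("need >= 2 control samples")
    table: dict[SubKey, np.ndarray] = {}
    for sample_index, calls in enumerate(control_call_sets):
        for row in calls.itertuples(index=False):
            vaf = float(row.vaf)
            if het_ceiling is not None and vaf > het_ceiling:
                continue  # likely a germline variant, keep out of background
            key = SubKey(row.chrom, int(row.pos), row.ref, row.alt)
            if key not in table:
                table[key] = np.zeros(n)
            table[key][sample_index] = vaf
    return table, n


def build_position_background(
    control_call_sets: list[pd.DataFrame],
    panel: ProbePanel,
    alpha: float = 0.999,
    outlier_drop: int = 1,
    het_ceiling: float | None = 0.25,
    kind: str = "internal",
) -> BackgroundModel:
    """Fit the per-(position, substitution) background from control calls.

    Every key observed in any control gets its own t distribution; the
    generic context fallback is fitted alongside so unseen keys stay
    governed.  Control VAFs above ``het_ceiling`` are treated as germline
    and contribute 0 instead.
    """
    table, n = _control_vaf_table(control_call_sets, het_ceiling)
    model = build_generic_background(
        control_call_sets, panel, alpha, het_ceiling=het_ceiling
    )
    model.kind = kind
    model.outlier_drop = outlier_drop
    for key, vafs in sorted(table.items()):
        if panel.locate(key.chrom, key.pos) is None:
            raise FilterError(f"control call {key.chrom}:{key.pos} outside panel")
        try:
            model.positional[key] = fit_background_distribution(
                vafs, alpha, outlier_drop
            )
        except InsufficientControlsError:
            continue
    return model


def build_generic_background(
    control_call_sets: list[pd.DataFrame],
    panel: ProbePanel,
    alpha: float = 0.999,
    het_ceiling: float | None = 0.25,
) -> BackgroundModel:
    """Pool control VAFs per complement-collapsed (context, alt) class.

    Every interior panel position belonging to a class contributes one
    VAF per control (0 when no call), so cold positions correctly pull
    the class background down -- this is exactly why a generic background
    underperforms the positional one at hot positions.
    """
    table, n = _control_vaf_table(control_call_sets, het_ceiling)
    class_vafs: dict[tuple[str, str], list[float]] = {}
    positions_per_class: dict[tuple[str, str], int] = {}
    for probe in panel:
        for off in range(1, probe.length - 1):
            pos = probe.start + off
            context = probe.region_seq[off - 1 : off + 2]
            ref = probe.region_seq[off]
            for alt in "ACGT":
                if alt == ref:
                    continue
                cls = collapse_context(context, alt)
                positions_per_class[cls] = positions_per_class.get(cls, 0) + 1
                key = SubKey(probe.chrom, pos, ref, alt)
                vafs = table.get(key)
                if vafs is None:
                    class_vafs.setdefault(cls, []).extend([0.0] * n)
                else:
                    class_vafs.setdefault(cls, []).extend(vafs.tolist())
    model = BackgroundModel(
        kind="generic", alpha=alpha, outlier_drop=0, n_controls=n
    )
    for cls, vafs in sorted(class_vafs.items()):
        model.generic[cls] = fit_background_distribution(
            np.array(vafs), alpha, outlier_drop=0
        )
    return model


# ---------------------------------------------------------------------------
# filtering


#: values of the ``filter_route`` column
ROUTE_POSITIONAL = "positional"
ROUTE_GENERIC = "generic-fallback"
ROUTE_EDGE = "edge-unmodeled"


def filter_variants(
    calls: pd.DataFrame,
    model: BackgroundModel,
    alpha: float | None = None,
    panel: ProbePanel | None = None,
) -> pd.DataFrame:
    """Flag calls whose VAF clears the high CI endpoint of their background.

    ``alpha`` overrides the model's alpha at query time (endpoints are
    recomputed from the stored t parameters).  Keys without a positional
    distribution are judged against the generic class fallback and get a
    distinct route flag; edge positions (no trinucleotide context) cannot
    be modelled and are never flagged significant.
    """
    alpha = model.alpha if alpha is None else alpha
    significant = np.zeros(len(calls), dtype=bool)
    routes = []
    thresholds = np.full(len(calls), np.nan)
    for i, row in enumerate(calls.itertuples(index=False)):
        if panel is not None and panel.locate(row.chrom, int(row.pos)) is None:
            raise FilterError(f"call {row.chrom}:{row.pos} outside panel")
        key = SubKey(row.chrom, int(row.pos), row.ref, row.alt)
        dist = model.positional.get(key)
        if dist is not None:
            route = ROUTE_POSITIONAL
        elif row.context != ".":
            cls = collapse_context(row.context, row.alt)
            dist = model.generic.get(cls)
            route = ROUTE_GENERIC if dist is not None else ROUTE_EDGE
        else:
            route = ROUTE_EDGE
        if dist is None:
            routes.append(route)
            continue
        _, high = ci_endpoints(dist, alpha)
        thresholds[i] = high
        significant[i] = float(row.vaf) > high
        routes.append(route)
    out = calls.copy()
    out["significant"] = significant
    out["filter_route"] = routes
    out["background_high"] = thresholds
    return out


def significant_call_counts(
    calls: pd.DataFrame, model: BackgroundModel, nines: list[int]
) -> pd.Series:
    """Significant-call count per alpha in a trailing-9s sweep."""
    counts = {}
    for k in nines:
        flagged = filter_variants(calls, model, alpha_from_nines(k))
        counts[k] = int(flagged["significant"].sum())
    return pd.Series(counts, name="significant_calls")


# ---------------------------------------------------------------------------
# spectra


@dataclass
class Spectrum:
    """Relative prevalence of substitution classes and contexts."""

    by_class: pd.Series  # 6 complement-collapsed classes, sums to 1
    by_context: pd.Series  # (context, alt) classes, sums to 1


def spectrum(
    calls: pd.DataFrame,
    collapse_complement: bool = True,
    weight: str = "count",
) -> Spectrum:
    """Substitution spectrum of a call set.

    ``weight='count'`` counts calls; ``weight='vaf'`` weights each call
    by its VAF (frequency-weighted prevalence).
    """
    if calls.empty:
        raise DataError("cannot compute a spectrum from zero calls")
    if weight not in ("count", "vaf"):
        raise ConfigError("weight must be 'count' or 'vaf'")
    weights = calls["vaf"].to_numpy() if weight == "vaf" else np.ones(len(calls))
    class_totals: dict[str, float] = {}
    context_totals: dict[tuple[str, str], float] = {}
    for w, row in zip(weights, calls.itertuples(index=False)):
        if collapse_complement:
            cls = collapse_substitution(row.ref, row.alt)
        else:
            cls = f"{row.ref}>{row.alt}"
        class_totals[cls] = class_totals.get(cls, 0.0) + w
        if row.context != ".":
            ctx_key = (
                collapse_context(row.context, row.alt)
                if collapse_complement
                else (row.context, row.alt)
            )
            context_totals[ctx_key] = context_totals.get(ctx_key, 0.0) + w
    by_class = pd.Series(class_totals, dtype=float)
    if collapse_complement:
        by_class = by_class.reindex(SUBSTITUTION_CLASSES, fill_value=0.0)
    by_class /= by_class.sum()
    by_context = pd.Series(context_totals, dtype=float).sort_index()
    if len(by_context):
        by_context /= by_context.sum()
    return Spectrum(by_class=by_class, by_context=by_context)
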