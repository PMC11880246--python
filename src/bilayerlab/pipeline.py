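"""End-to-end orchestration: simulate/load -> idealize -> histogram fit ->
I-V fit -> GHK permeability inversion, from a single validated config.

The pipeline mirrors the bilayer analysis workflow: per-voltage traces are
reduced to a unitary amplitude (two-Gaussian fit of the all-point
histogram) and an open probability (half-amplitude idealization with the
1.5 ms dead time); amplitudes across voltages give the slope conductance
and reversal potential; the reversal potential feeds the GHK inversion for
a permeability ratio.  Everything is deterministic given the config,
including its master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .amplitude_hist import all_point_histogram, fit_amplitude_gaussians
from .channel_sim import ChannelModel, simulate_trace
from .electrochem import (
    BathPair,
    PermeabilityResult,
    ghk_reversal_extended,
    ghk_reversal_monovalent,
    invert_divalent_ratio,
    invert_monovalent_ratio,
)
from .exceptions import BilayerlabError, ConfigError
from .idealization import estimate_baseline, idealize, open_probability
from .iv_fit import IVFitResult, build_iv, fit_iv
from .solutions import bath_from_config
from .traceio import read_trace, write_trace

__all__ = [
    "ChannelSpec",
    "BathSpec",
    "AnalysisSpec",
    "TraceRef",
    "PipelineConfig",
    "Report",
    "run_pipeline",
]


class ChannelSpec(BaseModel):
    """Simulator ground truth for simulate mode."""

    model_config = ConfigDict(extra="forbid")

    conductance_pS: float = Field(gt=0)
    e_rev_mV: Optional[float] = None  # derived from the bath when omitted
    k_open_per_s: float = Field(default=21.43, gt=0)
    k_close_per_s: float = Field(default=50.0, gt=0)
    n_channels: int = Field(default=1, ge=1)
    noise_sd_pA: float = Field(default=0.8, ge=0)
    filter_cutoff_Hz: Optional[float] = 1000.0
    filter_order: int = Field(default=4, ge=1)
    sampling_rate_Hz: float = Field(default=10000.0, gt=0)


class BathSpec(BaseModel):
    """Solution recipes per side plus the inversion to perform."""

    model_config = ConfigDict(extra="forbid")

    cis: dict[str, float]
    trans: dict[str, float]
    permeabilities: Optional[dict[str, float]] = None
    temperature_K: Optional[float] = None
    rt_over_f_mV: Optional[float] = None
    invert: Optional[Literal["monovalent", "divalent"]] = None
    reference_cation: str = "K+"
    target_anion: str = "Cl-"
    divalent_cation: Optional[str] = None
    include_anions: bool = False

    def build(self) -> BathPair:
        return bath_from_config(self.model_dump())


class AnalysisSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bin_width_pA: float = Field(default=0.05, gt=0)
    min_open_ms: float = Field(default=1.5, ge=0)
    threshold_frac: float = Field(default=0.5, gt=0, lt=1)
    weighted_iv: bool = False


class TraceRef(BaseModel):
    model_config = ConfigDict(extra="forbid")

    path: str
    holding_mV: Optional[float] = None  # sidecar value used when omitted


class PipelineConfig(BaseModel):
    """Validated description of one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["simulate", "load"]
    voltages_mV: Optional[list[float]] = None
    duration_s: float = Field(default=60.0, gt=0)
    channel: Optional[ChannelSpec] = None
    traces: Optional[list[TraceRef]] = None
    bath: Optional[BathSpec] = None
    analysis: AnalysisSpec = AnalysisSpec()
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        problems: list[str] = []
        if self.mode == "simulate":
            if self.seed is None:
                problems.append("simulate mode requires an explicit seed")
            if self.channel is None:
                problems.append("simulate mode requires a channel spec")
            if not self.voltages_mV:
                problems.append("simulate mode requires voltages_mV")
            elif len(set(self.voltages_mV)) < 2:
                problems.append("need at least 2 distinct voltages")
            if (
                self.channel is not None
                and self.channel.e_rev_mV is None
                and self.bath is None
            ):
                problems.append(
                    "channel.e_rev_mV omitted but no bath to derive it from"
                )
        else:
            if not self.traces:
                problems.append("load mode requires trace paths")
            else:
                for ref in self.traces:
                    if not Path(ref.path).exists():
                        problems.append(f"trace file not found: {ref.path}")
        if problems:
            raise ConfigError("; ".join(problems))
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        try:
            return cls(**yaml.safe_load(Path(path).read_text()))
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc

    def sha256(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class Report:
    """Machine-readable result of one pipeline run.

    Every number is traceable: per-voltage entries carry the fitted
    amplitude and Po, the I-V block the conductance and reversal potential
    derived from them, and the permeability block the inversion of that
    reversal potential.  Provenance records the config hash, package
    version and master seed.
    """

    per_voltage: list[dict]
    iv: Optional[dict]
    permeability: Optional[dict]
    provenance: dict
    errors: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def as_dict(self) -> dict:
        return {
            "per_voltage": self.per_voltage,
            "iv": self.iv,
            "permeability": self.permeability,
            "provenance": self.provenance,
            "errors": self.errors,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True))


def _analyze_trace(trace, analysis: AnalysisSpec) -> dict:
    baseline = estimate_baseline(trace, bin_width_pA=analysis.bin_width_pA)
    hist = all_point_histogram(trace, bin_width_pA=analysis.bin_width_pA)
    fit = fit_amplitude_gaussians(hist, baseline_pA=baseline)
    events = idealize(
        trace,
        unitary_amplitude_pA=fit.unitary_amplitude_pA,
        min_open_ms=analysis.min_open_ms,
        baseline_pA=baseline,
        threshold_frac=analysis.threshold_frac,
    )
    po = open_probability(events)
    n_channels = (
        trace.metadata.get("model", {}).get("n_channels", 1)
        if isinstance(trace.metadata, dict)
        else 1
    )
    return {
        "holding_mV": trace.holding_potential_mV,
        "baseline_pA": baseline,
        "amplitude_pA": fit.unitary_amplitude_pA,
        "closed_mean_pA": fit.closed.mean_pA,
        "open_mean_pA": fit.open.mean_pA,
        "closed_sd_pA": fit.closed.sd_pA,
        "open_sd_pA": fit.open.sd_pA,
        "po_label": "NPo" if n_channels > 1 else "Po",
        "po": po,
        "n_open_events": int(len(events.open_events)),
        "duration_ms": trace.duration_ms,
        "_events": events,
        "_trace": trace,
    }


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> Report:
    """Execute the configured pipeline and return its :class:`Report`.

    When ``out_dir`` is given, per-voltage trace TSVs (simulate mode),
    event CSVs and the report JSON are written there.  Stage failures are
    recorded in ``report.errors`` and downstream stages that depend on the
    failed one are skipped; callers (e.g. the CLI) treat a non-empty error
    list as failure.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    bath = config.bath.build() if config.bath is not None else None
    traces = []
    errors: list[dict] = []
    if config.mode == "simulate":
        chan = config.channel
        e_rev = chan.e_rev_mV
        if e_rev is None:
            has_divalent = any(
                s.valence == +2 and s.permeability > 0 for s in bath.species
            )
            e_rev = (
                ghk_reversal_extended(bath)
                if has_divalent
                else ghk_reversal_monovalent(bath)
            )
        model = ChannelModel(
            conductance_pS=chan.conductance_pS,
            e_rev_mV=e_rev,
            k_open_per_s=chan.k_open_per_s,
            k_close_per_s=chan.k_close_per_s,
            n_channels=chan.n_channels,
            noise_sd_pA=chan.noise_sd_pA,
            filter_cutoff_Hz=chan.filter_cutoff_Hz,
            filter_order=chan.filter_order,
            sampling_rate_Hz=chan.sampling_rate_Hz,
        )
        children = np.random.SeedSequence(config.seed).spawn(len(config.voltages_mV))
        for v, ss in zip(config.voltages_mV, children):
            sub_seed = int(ss.generate_state(1)[0] % 2**31)
            traces.append(
                simulate_trace(model, config.duration_s * 1000.0, v, sub_seed)
            )
    else:
        for ref in config.traces:
            trace = read_trace(ref.path)
            if ref.holding_mV is not None:
                object.__setattr__(trace, "holding_potential_mV", ref.holding_mV)
            traces.append(trace)

    per_voltage: list[dict] = []
    for trace in traces:
        try:
            per_voltage.append(_analyze_trace(trace, config.analysis))
        except BilayerlabError as exc:
            errors.append(
                {
                    "stage": "trace_analysis",
                    "holding_mV": trace.holding_potential_mV,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )

    iv_result: IVFitResult | None = None
    iv_dict = None
    if len({rec["holding_mV"] for rec in per_voltage}) >= 2:
        try:
            dataset = build_iv(
                [
                    {k: rec[k] for k in ("holding_mV", "amplitude_pA")}
                    for rec in per_voltage
                ]
            )
            iv_result = fit_iv(dataset, weighted=config.analysis.weighted_iv)
            iv_dict = {
                "conductance_pS": iv_result.conductance_pS,
                "conductance_se_pS": iv_result.conductance_se_pS,
                "e_rev_mV": iv_result.e_rev_mV,
                "e_rev_se_mV": iv_result.e_rev_se_mV,
                "n_points": iv_result.n_points,
                "rss_pA2": iv_result.rss,
            }
        except BilayerlabError as exc:
            errors.append({"stage": "iv_fit", "error": f"{type(exc).__name__}: {exc}"})
    elif per_voltage:
        errors.append(
            {"stage": "iv_fit", "error": "InputError: fewer than 2 usable voltages"}
        )

    perm_dict = None
    if (
        bath is not None
        and config.bath.invert is not None
        and iv_result is not None
    ):
        try:
            if config.bath.invert == "monovalent":
                perm: PermeabilityResult = invert_monovalent_ratio(
                    iv_result.e_rev_mV,
                    bath,
                    reference_cation=config.bath.reference_cation,
                    target_anion=config.bath.target_anion,
                )
            else:
                perm = invert_divalent_ratio(
                    iv_result.e_rev_mV,
                    bath,
                    reference_cation=config.bath.reference_cation,
                    divalent_cation=config.bath.divalent_cation,
                    include_anions=config.bath.include_anions,
                )
            perm_dict = {
                "numerator_species": perm.numerator_species,
                "denominator_species": perm.denominator_species,
                "ratio": perm.ratio,
                "e_rev_mV": perm.e_rev_mV,
                "rt_over_f_mV": perm.rt_over_f_mV,
                "method": perm.method,
            }
        except BilayerlabError as exc:
            errors.append(
                {"stage": "permeability", "error": f"{type(exc).__name__}: {exc}"}
            )

    if out is not None:
        for k, rec in enumerate(per_voltage):
            tag = f"v{k:02d}_{rec['holding_mV']:+.0f}mV"
            if config.mode == "simulate":
                write_trace(rec["_trace"], out / f"trace_{tag}.tsv")
            rec["_events"].to_csv(out / f"events_{tag}.csv")

    for rec in per_voltage:
        rec.pop("_events", None)
        rec.pop("_trace", None)

    report = Report(
        per_voltage=per_voltage,
        iv=iv_dict,
        permeability=perm_dict,
        provenance={
            "config_sha256": config.sha256(),
            "package_version": __version__,
            "seed": config.seed,
            "mode": config.mode,
        },
        errors=errors,
    )
    if out is not None:
        report.to_json(out / "report.json")
    return report
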