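"""End-to-end orchestration: simulate -> quantify -> compare -> report.

A :class:`RunConfig` carries every analysis threshold (defaulting to the
study constants: the -10 mV / 70 mV AP rule, 3-sigma calcium events,
3.5-s baseline and 35-s AUC windows, the 15 ms / 35 AP fast-spiking
classifier, and the -55 mV / 25 MOhm / 1000 MOhm QC cutoffs), one
master seed from which per-cell substreams are derived, and the group
layout of the experiment. Runs are bit-reproducible for a fixed config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calcium_quant as cq
from . import calcium_synth as cs
from . import ephys_features as ef
from . import ephys_synth as es
from .stats import GroupComparison, comparisons_to_table, mann_whitney_u, \
    mixed_two_way_anova

log = logging.getLogger("nphys")

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_QC_EMPTY = 3

EPHYS_METRICS = ("rmp_mv", "input_resistance_mohm", "capacitance_pf",
                 "rheobase_pa", "latency_ms", "first_isi_ms", "fahp_mv")
CALCIUM_METRICS = ("auc", "amplitude", "duration", "frequency")


@dataclass
class RunConfig:
    """All tunables of a pipeline run; defaults are the study constants."""

    ap_voltage_cutoff_mv: float = ef.AP_VOLTAGE_CUTOFF_MV        # -10
    ap_amplitude_cutoff_mv: float = ef.AP_AMPLITUDE_CUTOFF_MV    # 70
    event_sigma_multiple: float = cq.EVENT_SIGMA_MULTIPLE        # 3
    baseline_seconds: float = cq.BASELINE_SECONDS                # 3.5
    auc_window_seconds: float = cq.AUC_WINDOW_SECONDS            # 35
    frame_rate_hz: float = cq.DEFAULT_FRAME_RATE_HZ              # 1.7
    fs_tau_max_ms: float = ef.FS_TAU_MAX_MS                      # 15
    fs_min_aps_400pa: int = ef.FS_MIN_APS_400PA                  # 35
    qc_rmp_max_mv: float = ef.QC_RMP_MAX_MV                      # -55
    qc_access_resistance_max_mohm: float = ef.QC_ACCESS_RESISTANCE_MAX_MOHM
    qc_input_resistance_max_mohm: float = ef.QC_INPUT_RESISTANCE_MAX_MOHM
    seed: int = 0
    out_dir: str = "results"
    groups: dict = field(default_factory=dict)   # task-specific layout

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    root = np.random.default_rng(seed)
    return [np.random.default_rng(s) for s in root.integers(0, 2**31, n)]


# ---------------------------------------------------------------------
# electrophysiology runs
# ---------------------------------------------------------------------

def _simulate_cell(params: es.LifParams, cell_id: str,
                   genotype: str) -> list[ef.CurrentClampSweep]:
    sweeps = []
    rng = np.random.default_rng(params.seed)
    for proto in (ef.StepProtocolSpec.subthreshold_10pa(),
                  ef.StepProtocolSpec.excitability_20pa()):
        sw, _ = es.simulate_protocol(params, proto, rng=rng)
        sweeps.extend(sw)
    return sweeps


def run_ephys(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell extraction -> QC -> FS split -> per-class comparisons.

    ``config.groups`` maps genotype label to either ``{"manifests":
    [paths]}`` or ``{"n_cells": int, "lif": {LifParams overrides}}``.
    Returns the NeuronSummary table and the GroupComparison table.
    """
    if len(config.groups) < 1:
        raise ValueError("run_ephys needs at least one group")
    summaries: list[ef.NeuronSummary] = []
    for gi, (genotype, spec) in enumerate(sorted(config.groups.items())):
        if "manifests" in spec:
            sets = [ef.load_sweep_set(m) for m in spec["manifests"]]
            if not sets:
                raise ValueError(f"group {genotype}: empty manifest list")
            for meta, sweeps in sets:
                summaries.append(ef.summarize_cell(meta, sweeps))
        else:
            n = int(spec["n_cells"])
            streams = _substreams(config.seed + 7919 * gi, n)
            for ci, rng in enumerate(streams):
                params = es.LifParams(**{**spec.get("lif", {}),
                                         "seed": int(rng.integers(0, 2**31))})
                cell_id = f"{genotype}_{ci:03d}"
                sweeps = _simulate_cell(params, cell_id, genotype)
                summaries.append(ef.summarize_cell(
                    {"cell_id": cell_id, "genotype": genotype}, sweeps))
    summary_df = pd.DataFrame([s.as_row() for s in summaries])

    included = summary_df[summary_df["qc"] == "included"]
    for _, row in summary_df[summary_df["qc"] == "excluded"].iterrows():
        log.info("QC excluded %s: %s", row["cell_id"], row["qc_reasons"])

    comps: list[GroupComparison] = []
    genotypes = sorted(config.groups)
    if len(genotypes) == 2:
        ga, gb = genotypes
        for cls in ("FS", "non_FS"):
            sub = included[included["class_label"] == cls]
            a = sub[sub["genotype"] == ga]
            b = sub[sub["genotype"] == gb]
            if len(a) < 2 or len(b) < 2:
                log.info("comparison skipped for class %s: <2 cells/group", cls)
                continue
            for metric in EPHYS_METRICS:
                if metric not in sub.columns:
                    continue
                va = a[metric].dropna()
                vb = b[metric].dropna()
                if len(va) < 2 or len(vb) < 2:
                    continue
                c = mann_whitney_u(va, vb, metric=f"{cls}:{metric}")
                comps.append(c)
    comp_df = comparisons_to_table(comps)
    return summary_df, comp_df


def io_curve_anova(summaries_sweeps: dict[str, tuple[str, dict[float, int]]]
                   ) -> GroupComparison:
    """Mixed two-way ANOVA of AP counts across current steps.

    ``summaries_sweeps`` maps cell_id to (genotype, io_curve). The
    between factor is genotype; the within factor is the step amplitude.
    """
    rows = [{"subject": cid, "group": geno, "step": amp, "value": cnt}
            for cid, (geno, curve) in summaries_sweeps.items()
            for amp, cnt in curve.items()]
    return mixed_two_way_anova(pd.DataFrame(rows))


# ---------------------------------------------------------------------
# calcium runs
# ---------------------------------------------------------------------

def run_calcium(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell calcium summaries plus per-class group comparisons.

    ``config.groups`` maps genotype to ``{"traces": csv_path,
    "classes": {roi_id: class}}`` or ``{"classes": {class_name:
    {"n_cells": int, "ca": {CaSimParams overrides}}}}`` for synthetic
    populations.
    """
    rows = []
    for gi, (genotype, spec) in enumerate(sorted(config.groups.items())):
        traces: list[cq.FluorescenceTrace] = []
        if "traces" in spec:
            traces = cq.load_trace_table(spec["traces"],
                                         frame_rate=config.frame_rate_hz,
                                         classes=spec.get("classes"))
        else:
            for ki, (cls, cspec) in enumerate(sorted(
                    spec["classes"].items())):
                params = cs.CaSimParams(**{
                    "frame_rate": config.frame_rate_hz,
                    **cspec.get("ca", {})})
                tr, _ = cs.simulate_population(
                    params, int(cspec["n_cells"]),
                    seed=config.seed + 104729 * gi + 1299709 * ki,
                    cell_class=cls, roi_prefix=f"{genotype}_{cls}")
                traces.extend(tr)
        for tr in traces:
            dff = cq.compute_dff(tr, config.baseline_seconds)
            events = cq.detect_events(dff, config.event_sigma_multiple)
            s = cq.summarize_cell(
                dff, events, auc_window_seconds=config.auc_window_seconds)
            rows.append({"genotype": genotype, "roi_id": s.roi_id,
                         "cell_class": s.cell_class, "auc": s.auc,
                         "amplitude": s.amplitude, "duration": s.duration,
                         "frequency": s.frequency, "n_events": s.n_events})
    summary_df = pd.DataFrame(rows)

    comps: list[GroupComparison] = []
    genotypes = sorted(config.groups)
    if len(genotypes) == 2:
        ga, gb = genotypes
        for cls in sorted(summary_df["cell_class"].unique()):
            sub = summary_df[summary_df["cell_class"] == cls]
            a = sub[sub["genotype"] == ga]
            b = sub[sub["genotype"] == gb]
            if len(a) < 2 or len(b) < 2:
                log.info("calcium comparison skipped for class %s", cls)
                continue
            for metric in CALCIUM_METRICS:
                comps.append(mann_whitney_u(a[metric], b[metric],
                                            metric=f"{cls}:{metric}"))
    return summary_df, comparisons_to_table(comps)


# ---------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------

def report(config: RunConfig, tables: dict[str, pd.DataFrame],
           out_dir: str | Path | None = None) -> Path:
    """Write machine TSVs and a deterministic markdown summary.

    The report embeds the config hash and seed; optional metrics that
    are missing render as ``NA``. Rerunning with the same config yields
    identical bytes.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# nphys run report", "",
             f"config hash: `{config.digest()}`  ",
             f"seed: {config.seed}", ""]
    for name in sorted(tables):
        df = tables[name]
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
        lines.append(f"## {name}")
        lines.append("")
        lines.append(f"rows: {len(df)} -> `{path.name}`")
        if name.endswith("summary") and "qc" in df.columns:
            for _, r in df[df["qc"] == "excluded"].iterrows():
                lines.append(f"- excluded {r['cell_id']}: {r['qc_reasons']}")
        if "p" in df.columns:
            for _, r in df.iterrows():
                p = "NA" if pd.isna(r["p"]) else f"{r['p']:.4g}"
                lines.append(f"- {r['metric']}: {r['test']} "
                             f"stat={r['stat']:.4g} p={p} "
                             f"(n={r['n_a']}/{r['n_b']})")
        lines.append("")
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
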