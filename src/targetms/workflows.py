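"""End-to-end study workflows built from the library, controller, and quant
layers: the protein-standard spike-in benchmark, the gradient-warp
calibration check, multi-injection close-out campaigns, and the
targeted-vs-DDA sensitivity comparison.

These functions are what the command-line entry points and the acceptance
checks drive; each returns plain dictionaries of results so they can be
re-run under any seed.
"""

from __future__ import annotations

import numpy as np

from .assay import Assay, TargetList, build_assay
from .config import AcquisitionConfig
from .controller import run_dda_baseline, run_targeted
from .libraries import LibraryBundle
from .quant import (
    events_to_matrix,
    filter_quant_events,
    normalize_columns,
    subtract_blank_interference,
    summarize,
)
from .sim import (
    SampleScenario,
    library_from_scenario,
    make_adh1_scenario,
    make_proteome_scenario,
    unwarp_time,
    warp_gradient,
)


def quantified_keys(events, scheme: str) -> set[str]:
    """Peptide keys with at least one event passing the quantification
    filters for the given label scheme."""
    return {e.key for e in filter_quant_events(events, scheme)}


def assay_from_proteins(
    proteins: list[str],
    library: LibraryBundle,
    k: int = 3,
    config: AcquisitionConfig | None = None,
) -> Assay:
    return build_assay(TargetList(proteins=list(proteins), k=k), library, config)


# ---------------------------------------------------------------------------
# Spike-in ratio-recovery benchmark
# ---------------------------------------------------------------------------

def spikein_workflow(
    seed: int = 0,
    dilution_factor: float = 1.0,
    n_loading_controls: int = 24,
    counting_noise: bool = False,
    config: AcquisitionConfig | None = None,
) -> dict:
    """Full targeted run + quantification on the 1:2:4 spike-in design.

    Twelve spike peptides are targeted together with a set of 1:1 background
    peptides that serve as loading controls for column normalization. Blank
    channels flank the nine signal channels; their measured interference is
    subtracted per row before ratios are formed.
    """
    config = config or AcquisitionConfig()
    scenario = make_adh1_scenario(
        dilution_factor=dilution_factor, counting_noise=counting_noise, seed=seed
    )
    library = library_from_scenario(scenario, bin_width_s=config.bin_width_s)
    control_proteins = sorted(
        {a.protein for a in scenario.analytes if a.role == "background"}
    )[:n_loading_controls]
    n_spike = sum(1 for a in scenario.analytes if a.role == "spike")
    assay = build_assay(
        TargetList(proteins=["ADH1_SPIKE"] + control_proteins, k=n_spike),
        library,
        config,
    )
    log, events = run_targeted(scenario, assay, library, config, seed=seed + 1)
    kept = filter_quant_events(events, scenario.label_scheme)
    labels = scenario.channel_labels
    matrix = events_to_matrix(kept, labels)
    spike_keys = {a.key for a in scenario.analytes if a.role == "spike"}
    spike_rows = [k for k in matrix.index if k in spike_keys]
    control_rows = [k for k in matrix.index if k not in spike_keys]
    if control_rows:
        matrix = normalize_columns(matrix, reference_rows=control_rows)
    blanks = [labels[0], labels[-1]]
    matrix = subtract_blank_interference(matrix, blanks)
    groups = {
        "1x": list(labels[1:4]),
        "2x": list(labels[4:7]),
        "4x": list(labels[7:10]),
    }
    summary = summarize(matrix.loc[spike_rows], groups) if spike_rows else None
    out = {
        "scenario": scenario,
        "assay": assay,
        "log": log,
        "events": events,
        "matrix": matrix,
        "spike_rows": spike_rows,
        "summary": summary,
        "n_spike_quantified": len(spike_rows),
    }
    if summary is not None and len(summary):
        out["ratio_4_vs_1"] = float(summary["ratio_4x_vs_1x"].mean())
        out["ratio_2_vs_1"] = float(summary["ratio_2x_vs_1x"].mean())
    return out


# ---------------------------------------------------------------------------
# Calibration robustness under a gradient warp
# ---------------------------------------------------------------------------

def calibration_warp_check(
    seed: int = 0,
    exponent: float = 1.15,
    n_proteins: int = 250,
    gradient_s: float = 1800.0,
    config: AcquisitionConfig | None = None,
) -> dict:
    """Library from an unwarped run; acquisition on a monotonically warped
    gradient (t' = L * (t/L)**exponent). Reports the fraction of calibration
    episodes whose elution-point estimate lies within one bin of the true
    current bin of the warped run."""
    config = config or AcquisitionConfig()
    base = make_proteome_scenario(
        n_proteins=n_proteins,
        peptides_per_protein=1,
        abundance_log10_sigma=0.5,
        label_scheme="TMTpro16",
        gradient_s=gradient_s,
        counting_noise=True,
        seed=seed,
    )
    library = library_from_scenario(base, bin_width_s=config.bin_width_s)
    warped = warp_gradient(base, exponent)
    # small assay: calibration runs regardless of targets
    proteins = sorted({a.protein for a in base.analytes})[:5]
    assay = assay_from_proteins(proteins, library, config=config)
    log, _ = run_targeted(warped, assay, library, config, seed=seed + 1)
    errors = []
    for entry in log.calib_trace:
        if entry["c"] is None:
            continue
        true_bin = unwarp_time(entry["t"], gradient_s, exponent) / config.bin_width_s
        errors.append(entry["c"] - true_bin)
    errors = np.array(errors)
    within = float(np.mean(np.abs(errors) <= 1.0)) if len(errors) else 0.0
    return {
        "log": log,
        "errors": errors,
        "fraction_within_1_bin": within,
        "n_episodes": len(errors),
    }


# ---------------------------------------------------------------------------
# Targeted vs DDA sensitivity on a dynamic-range scenario
# ---------------------------------------------------------------------------

def sensitivity_comparison(
    seed: int = 0,
    n_proteins: int = 500,
    peptides_per_protein: int = 2,
    n_targets: int = 50,
    config: AcquisitionConfig | None = None,
) -> dict:
    """Run the targeted controller and the DDA baseline on one scenario and
    seed; count quantified target proteins per abundance quartile.

    Targets are drawn evenly across the protein abundance ranking so every
    quartile is represented.
    """
    config = config or AcquisitionConfig()
    scenario = make_proteome_scenario(
        n_proteins=n_proteins,
        peptides_per_protein=peptides_per_protein,
        seed=seed,
    )
    library = library_from_scenario(scenario, bin_width_s=config.bin_width_s)
    protein_abundance: dict[str, float] = {}
    for a in scenario.analytes:
        protein_abundance[a.protein] = (
            protein_abundance.get(a.protein, 0.0) + a.total_abundance
        )
    ranked = sorted(protein_abundance, key=lambda p: protein_abundance[p])
    idx = np.linspace(0, len(ranked) - 1, n_targets).round().astype(int)
    target_proteins = [ranked[i] for i in sorted(set(idx.tolist()))]
    # quartiles of the *target* set by abundance (ascending)
    ordered_targets = sorted(target_proteins, key=lambda p: protein_abundance[p])
    q = len(ordered_targets) // 4
    bottom_quartile = set(ordered_targets[: q or 1])

    assay = assay_from_proteins(target_proteins, library, k=peptides_per_protein,
                                config=config)
    run_seed = seed + 17
    _, targeted_events = run_targeted(scenario, assay, library, config, seed=run_seed)
    _, dda_events = run_dda_baseline(scenario, library, config, seed=run_seed)

    scheme = scenario.label_scheme
    target_set = set(target_proteins)
    targeted_prot = {
        e.protein for e in filter_quant_events(targeted_events, scheme)
        if e.protein in target_set
    }
    dda_prot = {
        e.protein for e in filter_quant_events(dda_events, scheme)
        if e.protein in target_set
    }
    return {
        "scenario": scenario,
        "target_proteins": target_proteins,
        "bottom_quartile": bottom_quartile,
        "targeted_quantified": targeted_prot,
        "dda_quantified": dda_prot,
        "targeted_bottom": len(targeted_prot & bottom_quartile),
        "dda_bottom": len(dda_prot & bottom_quartile),
        "targeted_total": len(targeted_prot),
        "dda_total": len(dda_prot),
    }


# ---------------------------------------------------------------------------
# Multi-injection close-out campaigns
# ---------------------------------------------------------------------------

def consecutive_injections(
    scenario: SampleScenario,
    assay: Assay,
    library: LibraryBundle,
    n_injections: int,
    config: AcquisitionConfig | None = None,
    seed: int = 0,
) -> dict:
    """Repeated injections of the same sample sharing one assay, so
    close-out accumulates; each injection draws fresh instrument noise."""
    config = config or AcquisitionConfig()
    runs = []
    cumulative: set[str] = set()
    for i in range(n_injections):
        log, events = run_targeted(scenario, assay, library, config, seed=seed + i)
        newly = quantified_keys(events, scenario.label_scheme)
        cumulative |= newly
        runs.append(
            {
                "log": log,
                "events": events,
                "quantified": newly,
                "n_targeted_scans": sum(
                    1 for s in log.scans if s.type in ("IT_PRM", "OT_MS2", "SPS_MS3")
                ),
            }
        )
    return {"runs": runs, "cumulative_quantified": cumulative}
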