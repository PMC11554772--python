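"""Configured, seeded benchmark pipeline: simulate/load -> split -> train ->
evaluate -> report bundle.

A run is fully determined by its configuration (every random draw is
seeded), and writes a self-describing bundle into the output directory:

* ``cohort.tsv`` (+ ``simulation_params.yaml`` when simulated)
* ``reports.tsv`` — tidy performance table, one row per test × stratum ×
  reference label (single tests, combined finals, and screening stages)
* ``rules.json`` — every trained rule with its training descriptor
* ``roc/`` — validation-set ROC points per marker × stratum × reference
* ``manifest.json`` — config hash, seeds, cohort counts, failures
* ``resolved_config.yaml`` and ``run.log``

Training touches only the "use" subset; every reported metric comes from
the held-out validation subset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    Cohort,
    read_cohort,
    read_split_assignment,
    split_cohort,
    with_split,
    write_cohort,
)
from .composition import (
    CombinedTestRule,
    K1N2_CALL_RULE,
    TestRule,
    evaluate_combined,
    evaluate_test,
    k1n2_reduction,
    rule_stratum,
    scored_labels_from_cohort,
    train_test_suite,
)
from .roc import SingleClassError, auc, bootstrap_auc_ci, roc_curve
from .simulate import default_params, simulate_cohort, write_params

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "kind", "test_name", "marker", "stratum", "reference_label", "objective",
    "cutpoint", "direction",
    "tp", "fp", "tn", "fn", "n_evaluated", "n_dropped_missing",
    "sensitivity", "specificity", "youden_j",
    "auc", "auc_ci_lower", "auc_ci_upper", "k1n2_reduction",
]


@dataclass
class BenchmarkConfig:
    """Everything a benchmark run depends on.

    Exactly one of ``cohort_path`` (load a cohort file) or ``scenario``
    (simulate one) must be set.  ``k1n2_cutoff`` switches the validator
    from the precomputed binary call column to a fixed cutoff on the
    continuous score; the validator is never refit either way.
    """

    cohort_path: str | None = None
    scenario: str | None = None
    n_samples: int = 348
    sim_seed: int = 0
    validation_fraction: float = 0.31
    split_seed: int = 0
    split_assignment_path: str | None = None
    markers: list[str] = field(default_factory=list)
    objectives: list[str] = field(default_factory=lambda: ["youden", "screening"])
    min_specificity: float = 0.3
    reference_labels: list[str] = field(default_factory=lambda: ["mutation_status"])
    k1n2_cutoff: float | None = None
    n_boot: int = 500
    boot_level: float = 0.95
    boot_seed: int = 0
    output_dir: str = "benchmark_out"

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.scenario is None):
            raise ValueError(
                "exactly one of cohort_path or scenario must be set"
            )
        if not 0 <= self.min_specificity < 1:
            raise ValueError("min_specificity must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml_text(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def validator_rule(self) -> TestRule:
        if self.k1n2_cutoff is None:
            return K1N2_CALL_RULE
        return TestRule(
            marker="k1n2_score", cutpoint=float(self.k1n2_cutoff),
            direction="greater",
            trained_on="fixed published-style cutoff (not refit)",
        )


def _load_cohort(config: BenchmarkConfig, outdir: Path) -> Cohort:
    if config.cohort_path is not None:
        logger.info("loading cohort from %s", config.cohort_path)
        cohort = read_cohort(config.cohort_path)
    else:
        logger.info("simulating %r cohort (n=%d, seed=%d)",
                    config.scenario, config.n_samples, config.sim_seed)
        params = default_params(config.scenario, n_samples=config.n_samples,
                                seed=config.sim_seed)
        cohort = simulate_cohort(params)
        write_params(params, outdir / "simulation_params.yaml")
    write_cohort(cohort, outdir / "cohort.tsv")
    return cohort


def _validation_view(cohort: Cohort, stratum: str) -> Cohort:
    histology = None if stratum == "pooled" else stratum
    return cohort.subset(histology=histology, split_group="validation")


def _single_report_row(rule: TestRule, fit, cohort: Cohort, reference: str,
                       config: BenchmarkConfig) -> dict | None:
    stratum = rule_stratum(rule)
    view = _validation_view(cohort, stratum)
    try:
        report = evaluate_test(rule, view, reference, stratum=stratum)
        data, _ = scored_labels_from_cohort(view, rule.marker, reference,
                                            direction=rule.direction)
        a = auc(data)
        lo, hi = bootstrap_auc_ci(data, n_boot=config.n_boot,
                                  level=config.boot_level,
                                  seed=config.boot_seed)
    except (SingleClassError, ValueError) as exc:
        logger.warning("evaluation failed (single, marker=%s stratum=%s): %s",
                       rule.marker, stratum, exc)
        return None
    row = report.to_dict()
    row["test_name"] = f"{rule.marker} [{fit.objective}]"
    row.update(kind="single", marker=rule.marker, objective=fit.objective,
               cutpoint=rule.cutpoint, direction=rule.direction,
               auc=a, auc_ci_lower=lo, auc_ci_upper=hi, k1n2_reduction=None)
    return row


def _combined_report_rows(rule: CombinedTestRule, cohort: Cohort,
                          reference: str) -> list[dict]:
    stratum = rule_stratum(rule)
    view = _validation_view(cohort, stratum)
    try:
        ev = evaluate_combined(rule, view, reference, stratum=stratum)
        reduction = k1n2_reduction(rule, view)
    except (SingleClassError, ValueError) as exc:
        logger.warning("evaluation failed (combined, screen=%s stratum=%s): %s",
                       rule.screen.marker, stratum, exc)
        return []
    rows = []
    for kind, report in (("combined_final", ev.final),
                         ("combined_screen", ev.screening)):
        row = report.to_dict()
        row.update(
            kind=kind, marker=rule.screen.marker,
            objective="screen_sens_at_min_spec",
            cutpoint=rule.screen.cutpoint, direction=rule.screen.direction,
            k1n2_reduction=reduction if kind == "combined_final" else None,
        )
        rows.append(row)
    return rows


def _write_roc_curves(cohort: Cohort, config: BenchmarkConfig,
                      outdir: Path) -> list[str]:
    rocdir = outdir / "roc"
    rocdir.mkdir(exist_ok=True)
    written = []
    for reference in config.reference_labels:
        for marker in config.markers:
            for stratum in ("pooled", "LUAD", "LUSC"):
                view = _validation_view(cohort, stratum)
                try:
                    data, _ = scored_labels_from_cohort(view, marker, reference)
                    curve = roc_curve(data)
                except (SingleClassError, ValueError):
                    continue
                name = f"{reference}__{marker}__{stratum}.tsv"
                pd.DataFrame(curve.to_records()).to_csv(
                    rocdir / name, sep="\t", index=False
                )
                written.append(f"roc/{name}")
    return written


def run_benchmark(config: BenchmarkConfig) -> Path:
    """Execute the full benchmark; returns the bundle directory.

    Deterministic given the config: running twice with identical
    configuration produces byte-identical bundles.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("nrf2screen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        cohort = _load_cohort(config, outdir)
        if config.split_assignment_path is not None:
            cohort = with_split(cohort,
                                read_split_assignment(config.split_assignment_path))
        else:
            cohort = split_cohort(cohort,
                                  validation_fraction=config.validation_fraction,
                                  seed=config.split_seed)

        markers = config.markers or (list(cohort.panel) + ["h_score"])
        config = dataclasses.replace(config, markers=markers)
        validator = config.validator_rule()

        rows: list[dict] = []
        all_rules: list[dict] = []
        failures: list[dict] = []
        for reference in config.reference_labels:
            logger.info("training suite against reference %s", reference)
            suite = train_test_suite(
                cohort, markers, objectives=config.objectives,
                reference_label=reference,
                min_specificity=config.min_specificity,
                validator=validator,
            )
            failures.extend(
                {"reference_label": reference, **dataclasses.asdict(f)}
                for f in suite.failures
            )
            for rule in suite.single_rules:
                fit = suite.fits[rule.trained_on]
                row = _single_report_row(rule, fit, cohort, reference, config)
                if row is not None:
                    rows.append(row)
                all_rules.append({"type": "single", "reference_label": reference,
                                  **rule.to_dict()})
            for crule in suite.combined_rules:
                rows.extend(_combined_report_rows(crule, cohort, reference))
                all_rules.append({"type": "combined", "reference_label": reference,
                                  **crule.to_dict()})

        reports = pd.DataFrame(rows, columns=REPORT_COLUMNS)
        reports.to_csv(outdir / "reports.tsv", sep="\t", index=False)
        with open(outdir / "rules.json", "w", encoding="utf-8") as fh:
            json.dump(all_rules, fh, indent=2, sort_keys=True)
            fh.write("\n")
        roc_files = _write_roc_curves(cohort, config, outdir)

        resolved = config.to_yaml_text()
        (outdir / "resolved_config.yaml").write_text(resolved, encoding="utf-8")
        split_counts = {
            g.value: sum(1 for v in cohort.split.values() if v is g)
            for g in sorted(set(cohort.split.values()), key=lambda g: g.value)
        }
        manifest = {
            "package": "nrf2screen",
            "version": __version__,
            "config_sha256": hashlib.sha256(resolved.encode()).hexdigest(),
            "seeds": {"sim_seed": config.sim_seed, "split_seed": config.split_seed,
                      "boot_seed": config.boot_seed},
            "n_samples": len(cohort),
            "histology_counts": cohort.histology_counts(),
            "split_counts": split_counts,
            "n_reports": len(reports),
            "n_rules": len(all_rules),
            "training_failures": failures,
            "outputs": sorted(
                ["cohort.tsv", "reports.tsv", "rules.json",
                 "resolved_config.yaml", "run.log"] + roc_files
                + (["simulation_params.yaml"] if config.scenario else [])
            ),
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("benchmark complete: %d report rows, %d rules, %d failures",
                    len(reports), len(all_rules), len(failures))
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir


def report_summary(bundle_dir: str | Path) -> str:
    """Human-readable markdown summary of a benchmark bundle.

    Every number shown is read back from ``reports.tsv`` in the bundle;
    nothing is recomputed.
    """
    bundle = Path(bundle_dir)
    reports_path = bundle / "reports.tsv"
    if not reports_path.exists():
        raise FileNotFoundError(f"no reports.tsv in {bundle}")
    reports = pd.read_csv(reports_path, sep="\t")
    lines = ["# Benchmark summary", ""]
    if reports.empty:
        lines.append("No tests were successfully trained and evaluated.")
        return "\n".join(lines)
    shown = reports[reports["kind"].isin(["single", "combined_final"])]
    lines += [
        "| test | stratum | reference | sens | spec | J | AUC | K1N2 spared |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for _, r in shown.iterrows():
        auc_txt = "" if pd.isna(r["auc"]) else f"{r['auc']:.3f}"
        red_txt = "" if pd.isna(r["k1n2_reduction"]) else f"{r['k1n2_reduction']:.1%}"
        lines.append(
            f"| {r['test_name']} | {r['stratum']} | {r['reference_label']} "
            f"| {r['sensitivity']:.3f} | {r['specificity']:.3f} "
            f"| {r['youden_j']:.3f} | {auc_txt} | {red_txt} |"
        )
    lines.append("")
    lines.append(f"{len(shown)} test evaluations "
                 f"({(reports['kind'] == 'single').sum()} single, "
                 f"{(reports['kind'] == 'combined_final').sum()} combined).")
    return "\n".join(lines)
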