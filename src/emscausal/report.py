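"""Descriptive reporting and end-to-end pipeline orchestration.

Renders the patient-characteristics table (counts/percentages per symptom
group, median/IQR age), the exclusion flowchart, and the analysis grid, and
runs simulate → build-cohort → estimate as one reproducible pipeline with a
manifest of seeds, hashes and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cohort import build_cohort, select_asa_population
from .config import AnalysisConfig, GeneratorConfig
from .estimator import run_analysis
from .synthetic import generate_registry

_BINARY_ROWS = (
    ("Medical service 1-1-2", "service_112"),
    ("Male sex", "male"),
    ("Type 2 diabetes", "t2d"),
    ("Hypertension", "hypertension"),
    ("Opioids", "opioid"),
    ("NSAID", "nsaid"),
    ("Previous ischemic heart disease", "ihd"),
    ("Previous myocardial infarction", "prev_mi"),
    ("Previous heart failure", "heart_failure"),
    ("Previous cancer", "cancer"),
    ("Previous renal disease", "renal"),
    ("Previous COPD", "copd"),
    ("Previous atrial fibrillation", "afib"),
    ("Immigrant/descendant", "immigrant"),
    ("ASA contraindication", "asa_contraindicated"),
)


def describe_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Patient-characteristics table by symptom group.

    One row per variable level with counts and percentages per group
    (percentages within a categorical variable sum to 100 per group), plus
    median [IQR] age.  Raw proportions are kept alongside the one-decimal
    display percentages.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    groups = {
        "chest": cohort[cohort["symptom_group"] == "chest"],
        "nonchest": cohort[cohort["symptom_group"] == "nonchest"],
        "total": cohort,
    }
    rows = []

    def add(variable, level, values):
        row = {"variable": variable, "level": level}
        for name, sub in groups.items():
            count, share = values(sub)
            row[f"{name}_n"] = count
            row[f"{name}_pct"] = round(100.0 * share, 1) if share is not None else None
            row[f"{name}_raw"] = share
        rows.append(row)

    add("Calls", "n", lambda s: (len(s), len(s) / len(cohort)))
    for label, col in _BINARY_ROWS:
        add(label, "yes", lambda s, col=col: (int((s[col] == 1).sum()),
                                              float((s[col] == 1).mean()) if len(s) else None))
    for level in ("basic", "intermediate", "advanced"):
        add("Educational level", level,
            lambda s, lv=level: (int((s["education"] == lv).sum()),
                                 float((s["education"] == lv).mean()) if len(s) else None))
    for level in ("STEMI", "NSTEMI", "other"):
        add("Infarct type", level,
            lambda s, lv=level: (int((s["infarct_type"] == lv).sum()),
                                 float((s["infarct_type"] == lv).mean()) if len(s) else None))
    for out in ("y30", "y1yr"):
        add("30-day mortality" if out == "y30" else "1-year combined outcome", "yes",
            lambda s, out=out: (int((s[out] == 1).sum()),
                                float((s[out] == 1).mean()) if len(s) else None))

    age_row = {"variable": "Age, years", "level": "median [IQR]"}
    for name, sub in groups.items():
        if len(sub):
            q1, med, q3 = np.percentile(sub["age"], [25, 50, 75])
            age_row[f"{name}_n"] = len(sub)
            age_row[f"{name}_pct"] = None
            age_row[f"{name}_raw"] = f"{med:.1f} [{q1:.1f}, {q3:.1f}]"
        else:
            age_row[f"{name}_n"] = 0
            age_row[f"{name}_pct"] = None
            age_row[f"{name}_raw"] = None
    rows.append(age_row)
    return pd.DataFrame(rows)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    seed: int
    config_hash: str
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text


def config_hash(config: GeneratorConfig) -> str:
    return hashlib.sha256(config.to_json().encode()).hexdigest()[:16]


def run_pipeline(
    config: GeneratorConfig,
    seed: int,
    out_dir,
    analysis_config: AnalysisConfig | None = None,
) -> RunManifest:
    """simulate → build-cohort → estimate → report, fully seeded.

    Writes the registry tables, cohort, exclusion log, descriptive table and
    analysis grid under ``out_dir`` and returns the manifest.  Identical
    (config, seed) reproduce identical outputs.
    """
    config.validate()
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, config_hash=config_hash(config), version=__version__)

    registry_dir = out / "registry"
    bundle = generate_registry(config, seed=seed)
    bundle.to_csv_dir(registry_dir)
    for name in bundle.TABLES:
        manifest.stage_counts[f"registry.{name}"] = len(getattr(bundle, name))
        manifest.outputs[f"registry.{name}"] = str(registry_dir / f"{name}.csv")

    cohort, log = build_cohort(bundle)
    cohort.to_csv(out / "cohort.csv", index=False)
    log.to_frame().to_csv(out / "exclusion_log.csv", index=False)
    manifest.stage_counts["cohort"] = len(cohort)
    manifest.stage_counts["exclusion.removed"] = log.total_removed
    manifest.outputs["cohort"] = str(out / "cohort.csv")
    manifest.outputs["exclusion_log"] = str(out / "exclusion_log.csv")
    if log.final_remaining != len(cohort):
        raise RuntimeError("exclusion log does not reconcile with the cohort size")

    table = describe_cohort(cohort)
    table.to_csv(out / "characteristics.csv", index=False)
    manifest.outputs["characteristics"] = str(out / "characteristics.csv")

    if analysis_config is None:
        analysis_config = AnalysisConfig()
    grid = run_analysis(cohort, config=analysis_config)
    grid.to_csv(out / "analysis_grid.csv", index=False)
    grid.to_json(out / "analysis_grid.json", orient="records", indent=2)
    manifest.stage_counts["analysis_cells"] = len(grid)
    manifest.stage_counts["asa_population"] = len(select_asa_population(cohort))
    manifest.outputs["analysis_grid"] = str(out / "analysis_grid.csv")

    manifest.to_json(out / "manifest.json")
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest
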