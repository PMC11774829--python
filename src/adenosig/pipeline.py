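"""End-to-end orchestration: simulate, analyze, report.

`run_analyze` chains the full method on a cohort directory: per sample,
intersect the two callers' VCFs, apply depth/VAF filters, build the
96-class catalogue against the reference, compute TMB, refit signature
exposures, combine the diagnostic signature groups (SBS18+SBS36, SBS30),
flag hotspots — then compute the group comparison table and hotspot
diagnostics across the cohort. Per-sample failures are isolated and
reported, not fatal. All outputs are TSV/JSON; re-running on unchanged
inputs with the same seed reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import pyfaidx

from . import catalogue as cat
from . import cohort_stats as cs
from . import hotspots as hs
from . import refit as rf
from .errors import ConfigurationError, RefitError
from .formatting import format_p, round_half_up
from .simulate import SYNTHETIC_BUILD, default_profiles, simulate_cohort

logger = logging.getLogger(__name__)

DEFAULT_PLAN: tuple[tuple[str, str], ...] = (
    ("MUTYH_adenoma", "control_adenoma"),
    ("MUTYH_CRC", "control_CRC"),
    ("NTHL1_adenoma", "control_adenoma"),
    ("NTHL1_CRC", "control_CRC"),
    ("MUTYH_adenoma", "MUTYH_CRC"),
    ("control_adenoma", "control_CRC"),
)

DEFAULT_DIAGNOSTIC_PAIRS: tuple[tuple[str, str], ...] = (
    ("MUTYH_adenoma", "control_adenoma"),
    ("MUTYH_CRC", "control_CRC"),
)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; study constants surface as defaults."""

    min_depth: int = 50
    min_vaf: float = 0.10
    capture_mb: float = 67.0
    hypermutation_threshold: float = 10.0
    bonferroni_m: int = 35
    signature_subset: tuple[str, ...] | None = None
    annealing: rf.AnnealingParams = field(default_factory=rf.AnnealingParams)
    comparison_plan: tuple[tuple[str, str], ...] = DEFAULT_PLAN
    diagnostic_pairs: tuple[tuple[str, str], ...] = DEFAULT_DIAGNOSTIC_PAIRS
    exclude_mmr_deficient_from: tuple[str, ...] = ("MUTYH_CRC",)
    build: str = SYNTHETIC_BUILD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_vaf < 0:
            raise ConfigurationError("thresholds must be non-negative")
        if self.capture_mb <= 0:
            raise ConfigurationError("capture_mb must be positive")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["annealing"] = dataclasses.asdict(self.annealing)
        return json.dumps(d, indent=2, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "annealing" in raw:
            raw["annealing"] = rf.AnnealingParams(**raw["annealing"])
        for key in ("comparison_plan", "diagnostic_pairs"):
            if key in raw:
                raw[key] = tuple(tuple(pair) for pair in raw[key])
        for key in ("signature_subset", "exclude_mmr_deficient_from"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def run_simulate(
    config: RunConfig,
    out_dir: str | Path,
    profiles=None,
    contig_length: int = 100_000,
) -> Path:
    """Simulate a cohort directory under ``config.seed``; echoes provenance."""
    out_dir = Path(out_dir)
    profiles = profiles if profiles is not None else default_profiles()
    cohort = simulate_cohort(profiles, out_dir, seed=config.seed,
                             contig_length=contig_length)
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump({"seed": config.seed, "config_hash": config.config_hash()}, fh, indent=2)
    logger.info("simulated cohort at %s (seed=%d, config=%s)",
                out_dir, config.seed, config.config_hash())
    return cohort


def analyze_sample(
    sample_id: str,
    vcf_a: Path,
    vcf_b: Path,
    reference,
    signatures: rf.SignatureMatrix,
    registry: Sequence[hs.HotspotDef],
    config: RunConfig,
) -> dict:
    """Run the per-sample pipeline; returns a features row plus objects."""
    calls_a = cat.read_somatic_vcf(vcf_a, sample_id, "callerA")
    calls_b = cat.read_somatic_vcf(vcf_b, sample_id, "callerB")
    consensus = cat.intersect_callers(calls_a, calls_b)
    kept = cat.filter_records(consensus, config.min_depth, config.min_vaf)
    logger.info(
        "%s: callerA=%d callerB=%d consensus=%d filtered_out=%d kept=%d",
        sample_id, len(calls_a), len(calls_b), len(consensus),
        len(consensus) - len(kept), len(kept),
    )
    catalogue = cat.build_catalogue(kept, reference, sample_id)
    tmb = cat.compute_tmb(catalogue, config.capture_mb, config.hypermutation_threshold)
    flags = hs.match_hotspots(kept, registry, config.build)
    row: dict = {
        "sample_id": sample_id,
        "snv_count": catalogue.snv_total,
        "indel_count": catalogue.indel_total,
        "tmb": tmb.tmb,
        "hypermutated": tmb.hypermutated,
    }
    exposure = None
    try:
        exposure = rf.refit_catalogue(catalogue, signatures, config.annealing)
        row["sbs18_36"] = 100.0 * rf.combined_exposure(exposure, ["SBS18", "SBS36"])
        row["sbs30"] = 100.0 * exposure["SBS30"]
        row["reconstruction_error"] = exposure.reconstruction_error
        row["low_confidence"] = exposure.low_confidence
    except RefitError:
        logger.warning("%s: zero SNVs after filtering, exposures undefined", sample_id)
        row["sbs18_36"] = None
        row["sbs30"] = None
        row["reconstruction_error"] = None
        row["low_confidence"] = True
    for name, flag in flags.items():
        row[f"flag_{name}"] = flag
    return {"row": row, "catalogue": catalogue, "tmb": tmb, "exposure": exposure,
            "flags": flags}


def run_analyze(config: RunConfig, cohort_dir: str | Path, out_dir: str | Path) -> Path:
    """Analyze a cohort directory into feature/exposure/comparison tables."""
    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(cohort_dir / "metadata.tsv", sep="\t")
    reference = pyfaidx.Fasta(str(cohort_dir / "reference.fa"))
    signatures = rf.load_signature_matrix(
        cohort_dir / "signatures.tsv", subset=config.signature_subset
    )
    registry = hs.load_registry(cohort_dir / "hotspots.json")

    rows, skipped = [], []
    catalogues: dict[str, tuple] = {}
    exposures: dict[str, rf.ExposureVector] = {}
    for rec in meta.itertuples():
        try:
            result = analyze_sample(
                rec.sample_id, cohort_dir / rec.vcf_a, cohort_dir / rec.vcf_b,
                reference, signatures, registry, config,
            )
        except Exception as exc:  # per-sample isolation
            logger.error("%s failed: %s", rec.sample_id, exc)
            skipped.append({"sample_id": rec.sample_id, "reason": str(exc)})
            continue
        row = result["row"]
        row["group"] = rec.group
        row["tissue"] = rec.tissue
        row["mmr_status"] = rec.mmr_status
        rows.append(row)
        catalogues[rec.sample_id] = (result["catalogue"], result["tmb"])
        if result["exposure"] is not None:
            exposures[rec.sample_id] = result["exposure"]

    features = pd.DataFrame(rows)
    front = ["sample_id", "group", "tissue", "mmr_status",
             "sbs18_36", "sbs30", "tmb", "snv_count", "indel_count"]
    features = features[front + [c for c in features.columns if c not in front]]
    features.to_csv(out_dir / "features.tsv", sep="\t", index=False)
    rf.write_exposures_tsv(exposures, out_dir / "exposures.tsv")
    cat.catalogue_frame(c for c, _ in catalogues.values()).to_csv(
        out_dir / "catalogues.tsv", sep="\t", index=False
    )
    cat.write_burden_tsv(catalogues, out_dir / "burden.tsv")

    plan = [
        pair for pair in config.comparison_plan
        if all(g in set(features["group"]) for g in pair)
    ]
    results, summaries = cs.comparison_table(
        features, plan, m=config.bonferroni_m,
        exclude_mmr_deficient_from=config.exclude_mmr_deficient_from,
    )
    cs.comparisons_frame(results).to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
    with open(out_dir / "comparisons.json", "w") as fh:
        json.dump(
            [
                {
                    "feature": r.feature, "group_a": r.group_a, "group_b": r.group_b,
                    "t": r.t, "df": r.df, "p": r.p, "p_adjusted": r.p_adjusted,
                    "cohens_d": r.cohens_d,
                }
                for r in results
            ],
            fh, indent=2,
        )

    diagnostics = {}
    for hotspot in registry:
        flag_col = f"flag_{hotspot.name}"
        if flag_col not in features.columns:
            continue
        for case_group, control_group in config.diagnostic_pairs:
            groups = set(features["group"])
            if case_group not in groups or control_group not in groups:
                continue
            case_flags = features.loc[features["group"] == case_group, flag_col]
            ctrl_flags = features.loc[features["group"] == control_group, flag_col]
            table = hs.diagnostic_2x2(case_flags.tolist(), ctrl_flags.tolist())
            entry = table.as_report()
            entry.update(hs.hotspot_association_test(table))
            diagnostics[f"{hotspot.name}|{case_group}_vs_{control_group}"] = entry
    with open(out_dir / "hotspot_summary.json", "w") as fh:
        json.dump(diagnostics, fh, indent=2)

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "config_hash": config.config_hash(),
                "n_samples": int(len(meta)),
                "n_analyzed": int(len(rows)),
                "skipped": skipped,
            },
            fh, indent=2,
        )
    if skipped:
        logger.warning("%d sample(s) skipped with reasons; see run_log.json", len(skipped))
    return out_dir


FEATURE_TITLES = {
    "sbs18_36": "SBS18+SBS36 (%)",
    "sbs30": "SBS30 (%)",
    "tmb": "TMB (mutations/Mb)",
    "indel_count": "INDEL count",
    "snv_count": "SNV count",
}


def run_report(analysis_dir: str | Path, path: str | Path | None = None) -> str:
    """Render the comparison tables as text with report rounding rules.

    Means and SDs print to one decimal, p-values to two significant
    figures, Cohen's d to one decimal.
    """
    analysis_dir = Path(analysis_dir)
    comp_path = analysis_dir / "comparisons.tsv"
    if not comp_path.exists():
        raise FileNotFoundError(f"no comparisons.tsv under {analysis_dir}")
    comp = pd.read_csv(comp_path, sep="\t")
    lines = ["Group comparison report", "=" * 70]
    if comp.empty:
        lines.append("no comparisons planned")
    for _, r in comp.iterrows():
        title = FEATURE_TITLES.get(r["feature"], r["feature"])
        d = r["cohens_d"]
        lines.append(
            f"{title}: {r['group_a']} (n={r['n_a']:.0f}, "
            f"mean {round_half_up(r['mean_a'], 1):g}, SD {round_half_up(r['sd_a'], 1):g}) "
            f"vs {r['group_b']} (n={r['n_b']:.0f}, "
            f"mean {round_half_up(r['mean_b'], 1):g}, SD {round_half_up(r['sd_b'], 1):g})"
        )
        lines.append(
            f"    p = {format_p(r['p'])}, adjusted p = {format_p(r['p_adjusted'])}, "
            f"Cohen's d = {round_half_up(d, 1):g}"
            if pd.notna(d)
            else f"    p = {format_p(r['p'])}, adjusted p = {format_p(r['p_adjusted'])}, "
                 f"Cohen's d undefined"
        )
    hs_path = analysis_dir / "hotspot_summary.json"
    if hs_path.exists():
        with open(hs_path) as fh:
            diagnostics = json.load(fh)
        if diagnostics:
            lines += ["", "Hotspot diagnostics", "-" * 70]
            for key, entry in diagnostics.items():
                ppv = entry["ppv"]
                npv = entry["npv"]
                lines.append(
                    f"{key}: tp={entry['tp']} fp={entry['fp']} "
                    f"fn={entry['fn']} tn={entry['tn']}  "
                    f"PPV={'NA' if ppv is None else f'{ppv:g} %'}  "
                    f"NPV={'NA' if npv is None else f'{npv:g} %'}  "
                    f"Fisher p={format_p(entry['fisher_p'])}"
                )
    text = "\n".join(lines) + "\n"
    out_path = Path(path) if path is not None else analysis_dir / "report.txt"
    out_path.write_text(text)
    return text
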