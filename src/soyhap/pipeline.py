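"""End-to-end orchestration: synthetic or user data in, one manifest out.

A run is described by a single YAML config (see :data:`DEFAULT_CONFIG`).
Stages execute in a fixed order — generate (optional), rmg,
photothermal, variants, haplotypes, blue, associate, frequencies — each
writing plain-text outputs into the run directory and a row-count entry
into the manifest. A stage failure aborts the run with the stage name;
outputs of completed stages are kept, as is a manifest of what ran.
Deterministic stages are byte-reproducible under an identical config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, association, haplotypes, io_formats, photothermal
from . import rmg as rmg_mod
from . import synthetic, variants as variants_mod
from .errors import SoyhapError

logger = logging.getLogger(__name__)

STAGE_ORDER = ("generate", "rmg", "photothermal", "variants", "haplotypes",
               "blue", "associate", "frequencies")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "soyhap_run",
    "synthetic": {},        # SyntheticConfig overrides; null to use inputs
    "inputs": None,         # paths dict when synthetic is null
    "stages": {},           # per-stage on/off overrides, default all on
    "blue_method": "reml",
    "alpha": 0.05,
    "calibration_site": "HH",
    "baseline_site": "HH",
}


class StageError(SoyhapError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    software_version: str
    stages: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"config_digest": self.config_digest, "seed": self.seed,
             "software_version": self.software_version, "stages": self.stages},
            indent=1, sort_keys=True)


def _digest(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    config = {**DEFAULT_CONFIG}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(loaded) - set(DEFAULT_CONFIG)
        if unknown:
            raise SoyhapError(f"unknown config keys: {sorted(unknown)}")
        config.update(loaded)
    if overrides:
        config.update(overrides)
    return config


def run_all(config: dict | str | Path) -> RunManifest:
    """Execute every enabled stage; returns the manifest (also written to
    ``<output_dir>/manifest.json``)."""
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_digest=_digest(config),
                           seed=int(config["seed"]),
                           software_version=__version__)
    enabled = {name: bool(config.get("stages", {}).get(name, True))
               for name in STAGE_ORDER}
    if config.get("synthetic") is None:
        enabled["generate"] = False

    state: dict = {"config": config, "out_dir": out_dir}
    for name in STAGE_ORDER:
        if not enabled[name]:
            logger.info("stage %s disabled; skipped", name)
            continue
        runner = _STAGES[name]
        try:
            entry = runner(state)
        except Exception as exc:
            (out_dir / "manifest.json").write_text(manifest.to_json())
            raise StageError(name, exc) from exc
        manifest.stages.append({"name": name, **entry})
        logger.info("stage %s: %s", name, entry.get("counts", {}))
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# Stages (each takes/extends the shared state dict)
# ---------------------------------------------------------------------------

def _stage_generate(state: dict) -> dict:
    config = state["config"]
    overrides = dict(config.get("synthetic") or {})
    overrides.setdefault("seed", int(config["seed"]))
    known = {f.name for f in dc_fields(synthetic.SyntheticConfig)}
    unknown = set(overrides) - known
    if unknown:
        raise SoyhapError(f"unknown synthetic config keys: {sorted(unknown)}")
    if "reference_rmg_range" in overrides:
        overrides["reference_rmg_range"] = tuple(
            overrides["reference_rmg_range"])
    syn_config = synthetic.SyntheticConfig(**overrides)
    bundle = synthetic.generate_bundle(syn_config)
    bundle_dir = state["out_dir"] / "bundle"
    paths = synthetic.write_bundle(bundle, bundle_dir)
    state["inputs"] = {key: str(p) for key, p in paths.items()}
    return {"outputs": sorted(str(p) for p in paths.values()),
            "counts": {"cultivars": syn_config.n_cultivars,
                       "genes": syn_config.n_genes,
                       "variants": len(bundle.variants),
                       "phenology_rows": len(bundle.phenology)}}


def _load_inputs(state: dict) -> None:
    if "loaded" in state:
        return
    inputs = state.get("inputs") or state["config"].get("inputs")
    if not inputs:
        raise SoyhapError("no inputs: enable the generate stage or supply "
                          "an 'inputs' path map in the config")
    state["environments"] = io_formats.read_environments(inputs["environments"])
    state["phenology"] = io_formats.read_phenology(inputs["phenology"],
                                                   state["environments"])
    state["references"] = io_formats.read_reference_cultivars(
        inputs["reference_cultivars"])
    state["genes"] = io_formats.read_gene_models(inputs["genes_gff"],
                                                 inputs["genes_fasta"])
    state["variants"] = io_formats.read_vcf(inputs["variants_vcf"])
    state["loaded"] = True


def _stage_rmg(state: dict) -> dict:
    _load_inputs(state)
    out_dir = state["out_dir"]
    site = state["config"]["calibration_site"]
    site_env_ids = {e.env_id for e in state["environments"] if e.site == site}
    ref_ids = {r.cultivar_id for r in state["references"]}
    ref_days: dict[str, list[int]] = {}
    for rec in state["phenology"]:
        if rec.cultivar_id in ref_ids and rec.env_id in site_env_ids \
                and rec.ve_r7_days is not None:
            ref_days.setdefault(rec.cultivar_id, []).append(rec.ve_r7_days)
    pairs = [(sum(d) / len(d), ref.assigned_rmg)
             for ref in state["references"]
             for d in [ref_days.get(ref.cultivar_id)] if d]
    model = rmg_mod.fit_rmg_model(pairs)
    panel = [rec for rec in state["phenology"]
             if rec.cultivar_id not in ref_ids]
    assignments = rmg_mod.classify_all(model, panel, env_ids=site_env_ids)
    matured = rmg_mod.matured_before_frost(panel, state["environments"])
    state["assignments"] = assignments
    state["panel_phenology"] = panel

    model_path = out_dir / "rmg_model.json"
    model_path.write_text(json.dumps({
        "slope": model.slope, "intercept": model.intercept,
        "r_squared": model.r_squared, "n_points": model.n_points,
        "residual_sd": model.residual_sd,
        "matured_counts": {env: len(cs) for env, cs in matured.items()},
    }, indent=1, sort_keys=True))
    assign_path = out_dir / "rmg_assignments.tsv"
    pd.DataFrame([{"cultivar": a.cultivar_id, "rmg": a.rmg,
                   "mg_label": a.mg_label} for a in assignments]
                 ).to_csv(assign_path, sep="\t", index=False)
    return {"outputs": [str(model_path), str(assign_path)],
            "counts": {"references_fit": model.n_points,
                       "cultivars_classified": len(assignments),
                       **{f"matured_{env}": len(cs)
                          for env, cs in sorted(matured.items())}}}


def _stage_photothermal(state: dict) -> dict:
    out_dir = state["out_dir"]
    baseline = state["config"]["baseline_site"]
    sens = photothermal.compute_sensitivities(
        state["panel_phenology"], state["environments"],
        baseline_site=baseline)
    state["sensitivities"] = sens
    rows = [{"cultivar": s.cultivar_id,
             "dtb_hh": s.dtb_hh, "dtb_bjc": s.dtb_bjc, "dtb_lbdl": s.dtb_lbdl,
             "ts_percent": None if s.ts_percent is None
             else round(s.ts_percent, 1),
             "ptcrs_percent": None if s.ptcrs_percent is None
             else round(s.ptcrs_percent, 1)} for s in sens]
    sens_path = out_dir / "sensitivities.tsv"
    pd.DataFrame(rows).to_csv(sens_path, sep="\t", index=False)
    corr = {}
    for stat in ("ts", "ptcrs"):
        r, p, n = photothermal.correlate_with_rmg(
            sens, state["assignments"], statistic=stat)
        corr[stat] = {"pearson_r": r, "p_value": p, "n": n}
    corr_path = out_dir / "sensitivity_correlations.json"
    corr_path.write_text(json.dumps(corr, indent=1, sort_keys=True))
    return {"outputs": [str(sens_path), str(corr_path)],
            "counts": {"cultivars": len(sens),
                       "ts_pairs": corr["ts"]["n"],
                       "ptcrs_pairs": corr["ptcrs"]["n"]}}


def _stage_variants(state: dict) -> dict:
    out_dir = state["out_dir"]
    retained, rejections = variants_mod.filter_variants(state["variants"])
    state["retained_variants"] = retained
    consequences = variants_mod.annotate_all(state["genes"], retained)
    state["consequences"] = consequences
    vcf_path = out_dir / "filtered.vcf"
    io_formats.write_vcf(retained, vcf_path)
    counts_path = out_dir / "filter_counts.json"
    counts_path.write_text(json.dumps(
        {"input": len(state["variants"]), "retained": len(retained),
         "rejections": rejections}, indent=1, sort_keys=True))
    cons_path = out_dir / "consequences.tsv"
    pd.DataFrame([{
        "gene": c.gene_id, "genomic_pos": c.position,
        "gene_offset": c.gene_offset, "cds_pos": c.cds_position,
        "ref": c.ref_allele, "alt": c.alt_allele,
        "codon_change": (f"{c.ref_codon}>{c.alt_codon}"
                         if c.ref_codon else ""),
        "aa_change": f"{c.ref_aa}>{c.alt_aa}" if c.ref_aa else "",
        "class": c.consequence_class,
    } for c in consequences]).to_csv(cons_path, sep="\t", index=False)
    return {"outputs": [str(vcf_path), str(counts_path), str(cons_path)],
            "counts": {"input": len(state["variants"]),
                       "retained": len(retained),
                       "annotated": len(consequences)}}


def _stage_haplotypes(state: dict) -> dict:
    out_dir = state["out_dir"]
    tables = {gene.gene_id: haplotypes.build_haplotypes(
        gene, state["retained_variants"]) for gene in state["genes"]}
    state["haplotype_tables"] = tables
    rows = []
    for gene_id, table in sorted(tables.items()):
        counts = table.counts()
        for label in sorted(table.haplotypes, key=lambda lab: int(lab[1:])):
            rows.append({
                "gene": gene_id, "haplotype": label,
                "allele_string": table.haplotypes[label],
                "n": counts[label],
                "is_reference": label == table.reference_label,
                "sites": ";".join(table.sites),
            })
    haps_path = out_dir / "haplotypes.tsv"
    pd.DataFrame(rows).to_csv(haps_path, sep="\t", index=False)
    members_path = out_dir / "haplotype_membership.tsv"
    member_rows = [{"gene": gene_id, "cultivar": cultivar,
                    "haplotype": label or ""}
                   for gene_id, table in sorted(tables.items())
                   for cultivar, label in sorted(table.membership.items())]
    pd.DataFrame(member_rows).to_csv(members_path, sep="\t", index=False)
    return {"outputs": [str(haps_path), str(members_path)],
            "counts": {gene_id: len(t.haplotypes)
                       for gene_id, t in sorted(tables.items())}}


def _stage_blue(state: dict) -> dict:
    out_dir = state["out_dir"]
    blues = association.compute_blue(state["panel_phenology"],
                                     method=state["config"]["blue_method"])
    state["blues"] = blues
    path = out_dir / "blues.tsv"
    pd.DataFrame([{"cultivar": b.cultivar_id, "blue_ve_r7_days": b.blue_value,
                   "n_environments": b.n_environments_observed}
                  for b in blues]).to_csv(path, sep="\t", index=False)
    return {"outputs": [str(path)], "counts": {"cultivars": len(blues)}}


def _stage_associate(state: dict) -> dict:
    out_dir = state["out_dir"]
    alpha = float(state["config"]["alpha"])
    results = {}
    for gene_id, table in sorted(state["haplotype_tables"].items()):
        try:
            results[gene_id] = association.associate_gene(
                state["blues"], table, alpha=alpha)
        except SoyhapError as exc:
            logger.warning("gene %s: association skipped (%s)", gene_id, exc)
    state["association_results"] = results
    rows, gene_rows = [], []
    for gene_id, res in sorted(results.items()):
        gene_rows.append({"gene": gene_id, "anova_f": res.anova_f,
                          "anova_p": res.anova_p,
                          "df_between": res.df_between,
                          "df_within": res.df_within})
        for hs in res.haplotype_stats:
            tag = ("early" if hs.label in res.early_set
                   else "late" if hs.label in res.late_set else "")
            rows.append({"gene": gene_id, "haplotype": hs.label,
                         "n": hs.n, "mean_blue": hs.mean_blue,
                         "letters": hs.letters, "early_late": tag})
    assoc_path = out_dir / "association.tsv"
    pd.DataFrame(rows).to_csv(assoc_path, sep="\t", index=False)
    anova_path = out_dir / "association_anova.tsv"
    pd.DataFrame(gene_rows).to_csv(anova_path, sep="\t", index=False)
    return {"outputs": [str(assoc_path), str(anova_path)],
            "counts": {"genes_tested": len(results),
                       "genes_significant": sum(
                           1 for r in results.values() if r.anova_p < alpha)}}


def _stage_frequencies(state: dict) -> dict:
    out_dir = state["out_dir"]
    mg_grouping = {a.cultivar_id: haplotypes.mg_bin(a.rmg)
                   for a in state["assignments"]}
    sites = sorted({e.site for e in state["environments"]})
    adapted = {site: rmg_mod.site_adapted_cultivars(
        state["panel_phenology"], state["environments"], site)
        for site in sites}
    baseline = state["config"]["baseline_site"]

    freq_rows, cmp_rows = [], []
    for gene_id, table in sorted(state["haplotype_tables"].items()):
        res = state.get("association_results", {}).get(gene_id)
        early = res.early_set if res is not None else frozenset()
        # maturity-group bins
        counts, freqs = haplotypes.haplotype_frequencies(table, mg_grouping)
        for group in sorted(counts):
            for label in sorted(counts[group], key=lambda lab: int(lab[1:])):
                freq_rows.append({"gene": gene_id, "grouping": "mg_bin",
                                  "group": group, "haplotype": label,
                                  "count": counts[group][label],
                                  "freq": freqs[group][label]})
        if early and {"MG 0-00", "MG 000-0000"} <= set(counts):
            cmp_rows.append(_comparison_row(
                counts, early, "MG 000-0000", "MG 0-00", gene_id, "mg_bin"))
        # site-adapted sets (cultivar may belong to several sites' sets,
        # so each site gets its own one-group pass)
        site_counts = {}
        for site in sites:
            grouping = {c: site for c in adapted[site]}
            c_site, f_site = haplotypes.haplotype_frequencies(table, grouping)
            if site in c_site:
                site_counts[site] = c_site[site]
                for label in sorted(c_site[site],
                                    key=lambda lab: int(lab[1:])):
                    freq_rows.append({
                        "gene": gene_id, "grouping": "site_adapted",
                        "group": site, "haplotype": label,
                        "count": c_site[site][label],
                        "freq": f_site[site][label]})
        if early:
            for site in sites:
                if site == baseline or site not in site_counts \
                        or baseline not in site_counts:
                    continue
                cmp_rows.append(_comparison_row(
                    site_counts, early, site, baseline, gene_id,
                    "site_adapted"))
    freq_path = out_dir / "haplotype_frequencies.tsv"
    pd.DataFrame(freq_rows).to_csv(freq_path, sep="\t", index=False)
    cmp_path = out_dir / "frequency_comparisons.tsv"
    pd.DataFrame(cmp_rows).to_csv(cmp_path, sep="\t", index=False)
    return {"outputs": [str(freq_path), str(cmp_path)],
            "counts": {"frequency_rows": len(freq_rows),
                       "comparisons": len(cmp_rows)}}


def _comparison_row(counts, hap_set, group_a, group_b, gene_id, grouping):
    cmp = haplotypes.compare_frequencies(counts, hap_set, group_a, group_b,
                                         gene_id=gene_id)
    return {"gene": gene_id, "grouping": grouping,
            "haplotype_set": "/".join(sorted(cmp.haplotype_set)),
            "group_a": group_a, "freq_a": cmp.freq_a, "n_a": cmp.total_a,
            "group_b": group_b, "freq_b": cmp.freq_b, "n_b": cmp.total_b,
            "statistic": cmp.statistic, "p_value": cmp.p_value,
            "method": cmp.method}


_STAGES = {
    "generate": _stage_generate,
    "rmg": _stage_rmg,
    "photothermal": _stage_photothermal,
    "variants": _stage_variants,
    "haplotypes": _stage_haplotypes,
    "blue": _stage_blue,
    "associate": _stage_associate,
    "frequencies": _stage_frequencies,
}
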