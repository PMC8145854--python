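"""End-to-end orchestration: simulate -> identify -> analyze -> report.

One RunConfig drives every stage; the consolidated report aggregates each
stage's summary with provenance (seed, config hash). Re-running with the same
config and seed reproduces all numbers.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .annotate import (
    annotate_mutation,
    build_gene_models,
    fitness_rate_summary,
    kaks_ratio,
    region_frequency_table,
    region_site_counts,
)
from .context import g_test_uniformity, gc_window_rates, gene_density_rates, trinucleotide_rates
from .filters import FilterConfig, calls_to_frame, identify_de_novo
from .genome import GenomeSpec, Reference, generate_reference
from .methylation import (
    build_site_table,
    enrichment_by_context,
    interaction_model,
    methylation_summary,
    strata_rates,
)
from .overlap import (
    merge_unique_mutations,
    overlap_significance,
    overlap_with_panel,
)
from .rates import conditional_spectrum, indel_profile, treatment_summary, ts_tv_summary
from .simulate import NoiseConfig, TreatmentSpec, emit_variant_calls, simulate_ma


@dataclass
class RunConfig:
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    treatments: list = field(
        default_factory=lambda: [
            TreatmentSpec(label="Control", snv_rate=5.3e-8, indel_rate=1.4e-8),
            TreatmentSpec(
                label="Heat",
                snv_rate=1.18e-7,
                indel_rate=4.9e-8,
                spectrum_weights=(0.52, 0.10, 0.07, 0.10, 0.14, 0.07),
                meth_multiplier=3.0,
                te_multiplier=2.0,
            ),
            TreatmentSpec(
                label="Warming",
                snv_rate=9.2e-8,
                indel_rate=3.4e-8,
                spectrum_weights=(0.50, 0.10, 0.08, 0.12, 0.13, 0.07),
                meth_multiplier=2.0,
                te_multiplier=1.5,
            ),
        ]
    )
    noise: NoiseConfig = field(
        default_factory=lambda: NoiseConfig(
            n_low_dp=3, n_single_strand=3, n_near_indel=2, n_indel_pair=2,
            n_het=3, n_in_background=3, n_background_het=2,
        )
    )
    filters: FilterConfig = field(default_factory=FilterConfig)
    panel_density: float = 0.05  # panel sites per accessible site
    panel_hit_fraction: float = 0.2  # unique mutations deliberately put in panel
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "genome" in raw:
            kwargs["genome"] = GenomeSpec(**raw["genome"])
        if "treatments" in raw:
            kwargs["treatments"] = [TreatmentSpec(**t) for t in raw["treatments"]]
        if "noise" in raw:
            kwargs["noise"] = NoiseConfig(**raw["noise"])
        if "filters" in raw:
            kwargs["filters"] = FilterConfig(**raw["filters"])
        for key in ("panel_density", "panel_hit_fraction", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def digest(self) -> str:
        blob = json.dumps(
            {
                "genome": asdict(self.genome),
                "treatments": [asdict(t) for t in self.treatments],
                "noise": asdict(self.noise),
                "filters": asdict(self.filters),
                "panel_density": self.panel_density,
                "panel_hit_fraction": self.panel_hit_fraction,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _synthetic_panel(reference: Reference, unique_keys, density, hit_fraction, rng):
    """A biallelic polymorphism panel: random sites plus planted overlaps."""
    panel = set()
    for chrom, seq in reference.chromosomes.items():
        sites = np.where(reference.callable_mask[chrom])[0]
        n = int(len(sites) * density)
        chosen = rng.choice(sites, size=n, replace=False)
        for pos0 in chosen:
            ref = seq[pos0]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
            panel.add((chrom, int(pos0) + 1, ref, alt))
    for key in unique_keys:
        if rng.random() < hit_fraction:
            panel.add(key)
    return sorted(panel)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage; writes stage outputs under outdir and returns the report."""
    out = io.ensure_dir(outdir)
    report = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.digest(),
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    }

    def stage(name):
        def wrap(fn):
            try:
                t0 = time.time()
                result = fn()
                report.setdefault("timings", {})[name] = round(time.time() - t0, 2)
                return result
            except Exception as exc:  # noqa: BLE001 - halt with stage name
                _dump(report, out)
                raise StageError(name, exc) from exc
        return wrap

    @stage("simulate")
    def _simulate():
        reference = generate_reference(
            GenomeSpec(**{**asdict(config.genome), "seed": config.seed})
        )
        io.write_fasta(reference.chromosomes, out / "reference.fa")
        io.write_gff3(reference.features, out / "annotation.gff3")
        io.write_bed_mask(reference.callable_mask, out / "callable.bed")
        io.write_methylation_tsv(reference.methylation, out / "methylation.tsv")
        data = {}
        for treatment in config.treatments:
            truth = simulate_ma(reference, treatment, seed=config.seed)
            samples, background, decoys = emit_variant_calls(
                reference, truth, config.noise, seed=config.seed
            )
            lengths = {c: len(s) for c, s in reference.chromosomes.items()}
            tdir = io.ensure_dir(out / treatment.label)
            for sid, recs in samples.items():
                io.write_vcf(recs, lengths, sid, tdir / f"{sid}.vcf")
            io.write_vcf(background, lengths, "background", tdir / "background.vcf")
            data[treatment.label] = (treatment, truth, samples, background, decoys)
        return reference, data

    reference, data = _simulate

    @stage("identify")
    def _identify():
        calls_by_treatment = {}
        for label, (treatment, truth, samples, background, _decoys) in data.items():
            if background is None:
                raise ValueError("missing background VCF")
            calls = []
            for sid, recs in samples.items():
                c, audit = identify_de_novo(
                    recs, background, config.filters,
                    reference=reference.chromosomes,
                    lineage_id=sid, treatment=label,
                )
                calls.extend(c)
                audit.to_csv(out / label / f"{sid}.audit.tsv", sep="\t", index=False)
            calls_to_frame(calls).to_csv(out / label / "calls.tsv", sep="\t", index=False)
            truth_n = sum(len(v) for v in truth.values())
            report.setdefault("identify", {})[label] = {
                "n_truth": truth_n,
                "n_calls": len(calls),
                "exact_match": {
                    (c.sample_id, *c.key) for c in calls
                } == {
                    (sid, *m.key) for sid, ms in truth.items() for m in ms
                },
            }
            calls_by_treatment[label] = calls
        return calls_by_treatment

    calls_by_treatment = _identify
    b = reference.n_callable()
    composition = reference.base_composition()

    @stage("rates")
    def _rates():
        section = {}
        for label, calls in calls_by_treatment.items():
            treatment = data[label][0]
            g = treatment.generations
            nl = treatment.n_lineages
            counts = {}
            for c in calls:
                counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
            per_lineage = [counts.get(sid, 0) for sid in data[label][1]]
            est = treatment_summary(per_lineage, [b] * nl, g)
            snvs = [c for c in calls if c.mtype == "SNV"]
            indels = [c for c in calls if c.mtype != "SNV"]
            spectrum = conditional_spectrum(snvs, composition, g, nl)
            spectrum.to_csv(out / label / "spectrum.tsv", sep="\t", index=False)
            section[label] = {
                "total_rate": est.to_dict(),
                "n_snv": len(snvs),
                "n_indel": len(indels),
                "ts_tv": ts_tv_summary(snvs, g, nl).to_dict(),
                "indels": indel_profile(indels, g, b * nl) if indels else None,
            }
        return section

    report["rates"] = _rates

    @stage("context")
    def _context():
        section = {}
        for label, calls in calls_by_treatment.items():
            treatment = data[label][0]
            snvs = [c for c in calls if c.mtype == "SNV"]
            table, excluded = trinucleotide_rates(
                snvs, reference, treatment.generations, treatment.n_lineages
            )
            table.to_csv(out / label / "context.tsv", sep="\t", index=False)
            at = table[table["focal"] == "AT"]
            entry = {"n_excluded": excluded}
            if at["count"].sum() > 0:
                exp = at["available_sites"] / at["available_sites"].sum()
                g_stat, p = g_test_uniformity(at["count"].to_numpy(), exp.to_numpy())
                entry["at_uniformity_g"] = g_stat
                entry["at_uniformity_p"] = p
            gc = gc_window_rates(calls, reference, treatment.generations)
            gc.to_csv(out / label / "gc_windows.tsv", sep="\t", index=False)
            bin_size = min(100_000, max(1000, config.genome.chrom_length // 10))
            gd, bins = gene_density_rates(
                calls, reference, treatment.generations, bin_size=bin_size
            )
            entry["gene_density"] = gd
            section[label] = entry
        return section

    report["context"] = _context

    models = build_gene_models(reference)
    site_counts = region_site_counts(reference, models)

    @stage("annotate")
    def _annotate():
        section = {}
        for label, calls in calls_by_treatment.items():
            treatment = data[label][0]
            annotated = [(c, annotate_mutation(c, reference, models)) for c in calls]
            table = region_frequency_table(
                annotated, site_counts, treatment.generations, treatment.n_lineages
            )
            table.to_csv(out / label / "regions.tsv", sep="\t", index=False)
            coding = [a for _c, a in annotated if a.region.startswith("exonic")]
            n_coding_by_sample: dict = {}
            for c, a in annotated:
                if a.region.startswith("exonic"):
                    n_coding_by_sample[c.sample_id] = n_coding_by_sample.get(c.sample_id, 0) + 1
            L = site_counts["exonic"]
            per_mu = [
                n_coding_by_sample.get(sid, 0) / (treatment.generations * L)
                for sid in data[label][1]
            ]
            nonsyn = sum(1 for a in coding if a.region in ("exonic:nonsynonymous", "exonic:stopgain", "exonic:stoploss"))
            syn = sum(1 for a in coding if a.region == "exonic:synonymous")
            cds_seqs = [m.cds_sequence(reference.chromosomes) for m in models]
            section[label] = {
                "fitness_rate": fitness_rate_summary(per_mu, L),
                "kaks": kaks_ratio(nonsyn, syn, cds_seqs),
                "n_coding": len(coding),
            }
        return section

    report["annotate"] = _annotate

    @stage("methylation")
    def _methylation():
        section = {"summary": methylation_summary(reference.methylation)}
        for label, calls in calls_by_treatment.items():
            treatment = data[label][0]
            site_table = build_site_table(reference, calls)
            enr = enrichment_by_context(calls, reference.methylation)
            enr.to_csv(out / label / "enrichment.tsv", sep="\t", index=False)
            entry = {
                "enrichment": enr.drop(columns=["table"], errors="ignore").to_dict("records"),
            }
            try:
                fit = interaction_model(site_table)
                entry["logistic"] = fit.to_dict("records")
            except ValueError as exc:
                entry["logistic_error"] = str(exc)
            strata = strata_rates(site_table, treatment.generations, treatment.n_lineages)
            strata.to_csv(out / label / "strata.tsv", sep="\t", index=False)
            entry["strata"] = strata.to_dict("records")
            section[label] = entry
        return section

    report["methylation"] = _methylation

    @stage("overlap")
    def _overlap():
        all_calls = [c for calls in calls_by_treatment.values() for c in calls]
        snvs, indels = merge_unique_mutations(all_calls)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
        panel = _synthetic_panel(
            reference, snvs + indels, config.panel_density, config.panel_hit_fraction, rng
        )
        panel_snvs = [k for k in panel if len(k[2]) == 1 == len(k[3])]
        result = overlap_with_panel(snvs, panel_snvs, b)
        p, pb = overlap_significance(
            result.n_positional_overlap, result.n_unique, result.panel_sites, b
        )
        result.fisher_p, result.bonferroni_p = p, pb
        return {
            "n_unique_snvs": len(snvs),
            "n_unique_indels": len(indels),
            "snv": result.to_dict(),
        }

    report["overlap"] = _overlap
    _dump(report, out)
    return report


def _dump(report, out: Path):
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    lines = ["# MA pipeline report", ""]
    for section, content in report.items():
        lines.append(f"## {section}")
        lines.append("```json")
        lines.append(json.dumps(content, indent=2, default=str))
        lines.append("```")
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))
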