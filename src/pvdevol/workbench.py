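"""File-driven pipeline: configuration, stage driver and run report.

Reads the external interfaces (protein FASTA, gene-order TSV, species-tree
Newick, phylogroup TSV, optional receptor FASTA), runs the full inference
chain, fits the Mk models to the resulting type character, and writes every
stage's tables plus a JSON run report. Re-execution with the same inputs,
config and seed is byte-identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from . import mk, phylo, pipeline
from .simulate import CladeData, SimulationConfig, simulate_clade

logger = logging.getLogger("pvdevol")


@dataclass
class PipelineConfig:
    nrps_fasta: str
    gene_order_tsv: str
    species_tree: str
    groups_tsv: str
    receptor_fasta: str | None = None
    out_dir: str = "pvdevol_out"
    seed: int = 0
    min_score: int = 7
    swap_low: float = 0.70
    swap_high: float = 0.90
    monophyly_fraction: float = 0.80
    mk_models: tuple = ("ER", "SYM")
    gamma_ncat: int = 10
    fit_gamma: bool = False
    include_nonproducers_as_missing: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self):
        for attr in ("nrps_fasta", "gene_order_tsv", "species_tree", "groups_tsv"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        if self.receptor_fasta and not Path(self.receptor_fasta).exists():
            raise FileNotFoundError(self.receptor_fasta)
        if not 0 < self.monophyly_fraction <= 1:
            raise ValueError("monophyly_fraction must be in (0, 1]")


@dataclass
class RunReport:
    seed: int
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    stages: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "counts": self.counts, "warnings": self.warnings,
             "stages": self.stages},
            indent=2, sort_keys=True,
        )


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)

    def stage(name, count):
        logger.info("%s: %d records", name, count)
        report.stages.append(name)
        report.counts[name] = count

    proteins = pio.read_fasta(config.nrps_fasta)
    stage("proteins", len(proteins))
    gene_order = pio.read_tsv(config.gene_order_tsv)
    tree = phylo.read_newick(config.species_tree)
    groups_df = pio.read_tsv(config.groups_tsv)
    groups = dict(zip(groups_df["strain"].astype(str), groups_df["group"]))
    receptors = None
    if config.receptor_fasta:
        receptors = {r.id: r.sequence for r in pio.read_fasta(config.receptor_fasta)}

    if not proteins:
        report.warnings.append("no producers: empty NRPS FASTA")
        stage("clusters", 0)
        (out / "report.json").write_text(report.to_json())
        return report

    result = pipeline.analyze_clade(
        proteins, gene_order, tree, groups, receptors=receptors,
        min_score=config.min_score, swap_low=config.swap_low,
        swap_high=config.swap_high, monophyly_fraction=config.monophyly_fraction,
    )
    stage("clusters", len(result.assemblies))
    stage("adomains", len(result.predictions))
    stage("types", result.registry.n_types)
    stage("shared_types", len(result.shared_types))
    stage("events", len(result.events))

    pio.write_tsv(result.types_table(), out / "types.tsv")
    pio.write_tsv(result.events_table(), out / "events.tsv")
    pred_rows = [
        {"domain_id": d, "substrate": p.substrate, "method": p.method,
         "code_score": p.code_vote[1], "clade_support": p.phylo_vote[1]}
        for d, p in sorted(result.predictions.items())
    ]
    pio.write_tsv(pd.DataFrame(pred_rows), out / "predictions.tsv")
    transfer_rows = [
        {"type": h.type_label, "groups": ",".join(h.groups), "verdict": h.verdict}
        for h in result.transfer_hypotheses
    ]
    pio.write_tsv(
        pd.DataFrame(transfer_rows, columns=["type", "groups", "verdict"]),
        out / "transfers.tsv",
    )

    # Mk models over the type character (producers only by default)
    tip_labels = {s: t for s, (t, _) in result.labels.items()}
    tree_tips = {l.taxon.label for l in tree.leaf_node_iter()}
    if config.include_nonproducers_as_missing:
        tip_labels.update({t: mk.MISSING for t in tree_tips - set(tip_labels)})
        char_tree = tree
    else:
        char_tree = tree.clone(depth=1)
        keep = [t for t in tree_tips if t in tip_labels]
        if len(keep) < len(tree_tips):
            char_tree.retain_taxa_with_labels(keep)
    states, levels = mk.states_from_labels(tip_labels)
    k = max(len(levels), 2)
    fits = []
    if len(levels) >= 2:
        for model in config.mk_models:
            fits.append(mk.fit_mk(char_tree, states, mk.MkModelSpec(k=k, parameterization=model)))
        if config.fit_gamma:
            fits.append(
                mk.fit_mk(char_tree, states,
                          mk.MkModelSpec(k=k, parameterization="SYM", gamma=True,
                                         ncat=config.gamma_ncat))
            )
        comparison = mk.compare_models(fits)
        best = comparison.ranking[0]
        recon = mk.marginal_ancestral_states(char_tree, states, best.q_matrix)
        fit_report = {
            "states": levels,
            "models": [
                {"model": f.spec.name, "logL": f.log_likelihood, "AIC": f.aic,
                 "n_params": f.n_params, "rates": list(map(float, f.rates))}
                for f in comparison.ranking
            ],
            "plotted_model": comparison.ranking[0].spec.name,
        }
        (out / "mk_fit.json").write_text(json.dumps(fit_report, indent=2))
        rows = [
            {"node": n, **{levels[i]: p[i] for i in range(len(levels))}}
            for n, p in sorted(recon.items())
        ]
        pio.write_tsv(pd.DataFrame(rows), out / "ancestral_states.tsv")
        stage("mk_models", len(fits))
    else:
        report.warnings.append("single pyoverdine type; Mk stage skipped")

    if result.receptor_concordance is not None:
        (out / "receptor_concordance.json").write_text(
            json.dumps({"concordance": result.receptor_concordance,
                        "per_type": result.receptor_per_type}, indent=2)
        )
    (out / "report.json").write_text(report.to_json())
    return report


def write_simulated_bundle(clade: CladeData, out_dir) -> dict:
    """Write a simulated clade as the pipeline's input files plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins, rows = clade.proteins()
    pio.write_fasta(proteins, out / "nrps.fasta")
    pio.write_tsv(pd.DataFrame(rows), out / "gene_order.tsv")
    phylo.write_newick(clade.tree, out / "species.nwk")
    pio.write_tsv(
        pd.DataFrame(
            [{"strain": s, "group": g} for s, g in sorted(clade.groups.items())]
        ),
        out / "groups.tsv",
    )
    from .architecture import ProteinRecord

    pio.write_fasta(
        [ProteinRecord(s, seq) for s, seq in sorted(clade.receptors.items())],
        out / "receptors.fasta",
    )
    pio.write_tsv(
        pd.DataFrame(
            [
                {"kind": e.kind, "donor": e.donor or "", "recipient": e.recipient,
                 "module_ordinals": ",".join(map(str, e.module_ordinals)),
                 "timestamp": e.timestamp}
                for e in clade.event_log
            ],
            columns=["kind", "donor", "recipient", "module_ordinals", "timestamp"],
        ),
        out / "event_log.tsv",
    )
    manifest = {
        "n_strains": len(clade.clusters),
        "n_proteins": len(proteins),
        "n_adomains": sum(len(c.modules) for c in clade.clusters.values()),
        "n_events": len(clade.event_log),
        "seed": clade.config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def simulate_bundle(seed: int, out_dir, n_tips: int = 12, events=None) -> dict:
    """Simulate a clade (optionally with events) and write the pipeline bundle."""
    config = SimulationConfig(n_tips=n_tips, seed=seed)
    clade = simulate_clade(config, event_requests=events or [])
    return write_simulated_bundle(clade, out_dir)
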