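"""End-to-end orchestration: simulate -> collect -> phylotype -> classify ->
design -> evaluate, with a manifest for reproducibility and resume.

Every stage writes TSV (or FASTA/JSON) outputs into the run directory and the
manifest records parameters and seeds, so each report cell can be recomputed
by calling the owning module directly.  Reruns with an identical config are
byte-identical; completed stages are skipped on resume.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import classifier as clf
from . import diversity, phylo, primers, synthetic
from .seq_io import Alignment, SequenceRecord, length_filter, revcomp, write_fasta

__all__ = ["PipelineConfig", "run_pipeline", "summarize_clone_table"]


def _default_windows(
    target: str, clades: Sequence[str], alignment_length: int
) -> tuple[synthetic.PlantedWindow, ...]:
    return (
        # taxon-specific site: retained in (almost) all target sequences only
        synthetic.PlantedWindow(
            start=int(0.35 * alignment_length),
            length=19,
            clades=(target,),
            retention={target: 0.95},
        ),
        # universal site: retained everywhere; supplies the reverse partner
        synthetic.PlantedWindow(
            start=int(0.64 * alignment_length),
            length=18,
            clades=tuple(clades),
            retention={c: 1.0 for c in clades},
        ),
    )


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters of one synthetic end-to-end run."""

    rng_seed: int = 0
    clade_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "CladeA": 60, "CladeB": 45, "CladeC": 45, "CladeD": 40, "CladeE": 40
        }
    )
    target_clade: str = "CladeA"
    alignment_length: int = 1400
    intra_divergence: float = 0.08
    inter_divergence: float = 0.28
    partial_fraction: float = 0.0
    min_length: int = 1200
    backbone_per_clade: int = 6
    bootstrap_reps: int = 100
    support_threshold: float = 80.0
    batch_size: int = 500
    phylotype_threshold: float = diversity.DEFAULT_PHYLOTYPE_THRESHOLD
    classifier_k: int = 8
    candidate_length_range: tuple[int, int] = (18, 20)
    min_amplicon: int = 400
    stages: tuple[str, ...] = (
        "simulate", "collect", "phylotype", "rarefy", "train",
        "classify", "consensus", "design", "evaluate", "pair_evaluate",
    )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        obj = json.loads(Path(path).read_text())
        if "clade_sizes" in obj:
            obj["clade_sizes"] = dict(obj["clade_sizes"])
        for key in ("candidate_length_range", "stages"):
            if key in obj:
                obj[key] = tuple(obj[key])
        return cls(**obj)

    def generator_config(self) -> synthetic.GeneratorConfig:
        clades = sorted(self.clade_sizes)
        return synthetic.GeneratorConfig(
            clade_sizes=dict(self.clade_sizes),
            target_clade=self.target_clade,
            alignment_length=self.alignment_length,
            intra_divergence=self.intra_divergence,
            inter_divergence=self.inter_divergence,
            windows=_default_windows(self.target_clade, clades, self.alignment_length),
            partial_fraction=self.partial_fraction,
            rng_seed=self.rng_seed,
        )


def summarize_clone_table(
    per_library: Iterable[tuple[str, float]] | pd.DataFrame,
    group_col: str = "group",
    value_col: str = "percent",
) -> dict[str, tuple[float, float | None, int]]:
    """Mean and sample (n-1) standard deviation of clone-library percentages
    per group (e.g. per reverse primer), each half-up rounded to 1 decimal.

    Accepts (group, percentage) pairs or a DataFrame with those columns; the
    SD is ``None`` for singleton groups.
    """
    if isinstance(per_library, pd.DataFrame):
        pairs = list(zip(per_library[group_col], per_library[value_col]))
    else:
        pairs = list(per_library)
    groups: dict[str, list[float]] = {}
    for g, v in pairs:
        groups.setdefault(str(g), []).append(float(v))
    if not groups:
        raise ValueError("no values to summarize")
    out: dict[str, tuple[float, float | None, int]] = {}
    for g, vals in groups.items():
        arr = np.asarray(vals)
        mean = primers.round_half_up(float(arr.mean()))
        sd = (
            primers.round_half_up(float(arr.std(ddof=1))) if len(arr) >= 2 else None
        )
        out[g] = (mean, sd, len(arr))
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _write(path: Path, text: str) -> None:
    path.write_text(text)


class _Manifest:
    def __init__(self, path: Path, config: PipelineConfig) -> None:
        self.path = path
        cfg = dataclasses.asdict(config)
        cfg["clade_sizes"] = dict(cfg["clade_sizes"])
        cfg["stages"] = list(cfg["stages"])
        cfg["candidate_length_range"] = list(cfg["candidate_length_range"])
        if path.exists():
            old = json.loads(path.read_text())
            if old.get("config") == cfg:
                self.state = old
                return
        self.state = {"config": cfg, "completed": []}
        self._flush()

    def done(self, stage: str) -> bool:
        return stage in self.state["completed"]

    def mark(self, stage: str) -> None:
        if stage not in self.state["completed"]:
            self.state["completed"].append(stage)
        self._flush()

    def _flush(self) -> None:
        self.path.write_text(json.dumps(self.state, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, object]:
    """Execute the configured stages in order, reusing completed outputs.

    Returns the in-memory artefacts of the stages that ran (keyed by stage
    name) for programmatic use; files are the canonical record.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json", config)
    artefacts: dict[str, object] = {}
    stages = config.stages

    # ---- simulate --------------------------------------------------------
    pool, truth = synthetic.simulate_pool(config.generator_config())
    if "simulate" in stages:
        if not manifest.done("simulate"):
            write_fasta(pool, out / "pool.fasta")
            _write(
                out / "taxonomy.tsv",
                "".join(f"{r.id}\t{r.taxon_label}\n" for r in pool),
            )
            _write(out / "truth.json", truth.to_json() + "\n")
            manifest.mark("simulate")
        artefacts["simulate"] = (pool, truth)

    # backbone/query split shared by all downstream stages
    filtered = length_filter(list(pool), config.min_length)
    per_clade: dict[str, list[SequenceRecord]] = {}
    outgroup = None
    for r in filtered:
        if r.taxon_label == "Outgroup":
            outgroup = r
            continue
        per_clade.setdefault(r.taxon_label, []).append(r)
    backbone_records: list[SequenceRecord] = []
    query_records: list[SequenceRecord] = []
    for clade in sorted(per_clade):
        recs = per_clade[clade]
        backbone_records.extend(recs[: config.backbone_per_clade])
        query_records.extend(r.with_label(None) for r in recs[config.backbone_per_clade :])
    if outgroup is not None:
        backbone_records.append(outgroup)
    backbone = Alignment(tuple(backbone_records))

    result: phylo.CollectionResult | None = None
    if "collect" in stages:
        if manifest.done("collect") and (out / "collection.tsv").exists():
            df = pd.read_csv(out / "collection.tsv", sep="\t")
            collected = frozenset(df.loc[df["class"] == "target", "id"])
            unclassified = frozenset(df.loc[df["class"] == "unclassified", "id"])
            nontarget = frozenset(df.loc[df["class"] == "nontarget", "id"])
            result = phylo.CollectionResult(
                target_ids=collected | {r.id for r in backbone if r.taxon_label == config.target_clade},
                nontarget_ids=nontarget,
                unclassified_ids=unclassified,
                rounds=(),
                batch_monophyly=(),
                final_monophyly_support=None,
            )
        else:
            params = phylo.CollectionParams(
                batch_size=config.batch_size,
                support_threshold=config.support_threshold,
                bootstrap_reps=config.bootstrap_reps,
                rng_seed=config.rng_seed,
                outgroup_id=outgroup.id if outgroup is not None else None,
            )
            result = phylo.iterative_collect(
                backbone, query_records, config.target_clade, params
            )
            lines = ["id\tclass"]
            for r in query_records:
                if r.id in result.target_ids:
                    cls = "target"
                elif r.id in result.unclassified_ids:
                    cls = "unclassified"
                else:
                    cls = "nontarget"
                lines.append(f"{r.id}\t{cls}")
            _write(out / "collection.tsv", "\n".join(lines) + "\n")
            _write(out / "collection_audit.tsv", result.audit_tsv())
            manifest.mark("collect")
        artefacts["collect"] = result

    # the working "local database": backbone plus collected queries as target
    database: list[SequenceRecord] = list(backbone_records)
    if result is not None:
        collected_q = [
            r.with_label(config.target_clade)
            for r in query_records
            if r.id in result.target_ids
        ]
        database += collected_q
    target_db = [
        r for r in database if r.taxon_label == config.target_clade
    ]

    phylotypes: diversity.PhylotypeSet | None = None
    dm_target: phylo.DistanceMatrix | None = None
    if "phylotype" in stages and target_db:
        dm_target = phylo.distance_matrix(Alignment(tuple(target_db)))
        dend = diversity.upgma(dm_target)
        phylotypes = diversity.cut_phylotypes(
            dend,
            config.phylotype_threshold,
            dm=dm_target,
            records={r.id: r for r in target_db},
        )
        if not manifest.done("phylotype"):
            _write(out / "phylotypes.tsv", phylotypes.membership_tsv())
            manifest.mark("phylotype")
        artefacts["phylotype"] = phylotypes

    if "rarefy" in stages and phylotypes is not None:
        curve = diversity.rarefaction_curve(phylotypes.sizes())
        if not manifest.done("rarefy"):
            _write(out / "rarefaction.tsv", curve.tsv())
            manifest.mark("rarefy")
        artefacts["rarefy"] = curve

    model: clf.WordModel | None = None
    if "train" in stages:
        model = clf.train(database, k=config.classifier_k, rank="phylum")
        if not manifest.done("train"):
            model.save(out / "classifier.json")
            manifest.mark("train")
        artefacts["train"] = model

    if "classify" in stages and model is not None:
        holdout = [r for r in query_records if result is None or r.id not in result.target_ids]
        calls = clf.classify_records(model, holdout)
        if not manifest.done("classify"):
            lines = ["id\tlabel\tlog_score\torientation"]
            for rid in sorted(calls):
                c = calls[rid]
                score = f"{max(c.scores.values()):.4f}" if c.scores else ""
                lines.append(f"{rid}\t{c.label or 'unclassifiable'}\t{score}\t{c.orientation}")
            _write(out / "classifications.tsv", "\n".join(lines) + "\n")
            manifest.mark("classify")
        artefacts["classify"] = calls

    consensus: primers.Consensus | None = None
    if "consensus" in stages and phylotypes is not None:
        reps = [r for r in target_db if r.id in set(phylotypes.representatives)]
        consensus = primers.consensus_majority(Alignment(tuple(reps)))
        if not manifest.done("consensus"):
            _write(out / "consensus.txt", consensus.residues + "\n")
            manifest.mark("consensus")
        artefacts["consensus"] = consensus

    top: primers.Candidate | None = None
    if "design" in stages and consensus is not None:
        candidates = primers.enumerate_candidates(
            consensus,
            database,
            target=config.target_clade,
            length_range=config.candidate_length_range,
        )
        top = candidates[0] if candidates else None
        if not manifest.done("design"):
            lines = ["rank\tposition\tsequence\tcoverage\tmax_tolerance\tstructure_violations"]
            for rank, c in enumerate(candidates[:50], 1):
                lines.append(
                    f"{rank}\t{c.position}\t{c.residues}"
                    f"\t{primers.round_half_up(c.coverage)}"
                    f"\t{primers.round_half_up(c.max_tolerance)}"
                    f"\t{c.structure_violations}"
                )
            _write(out / "candidates.tsv", "\n".join(lines) + "\n")
            manifest.mark("design")
        artefacts["design"] = candidates

    designed: primers.Primer | None = None
    if top is not None:
        designed = primers.Primer(
            name="DESIGNED-1",
            residues=top.residues,
            target=config.target_clade,
            role="forward",
        )

    if "evaluate" in stages and designed is not None:
        table = primers.specificity_table([designed], database)
        if not manifest.done("evaluate"):
            table.to_csv(out / "specificity.tsv", sep="\t", index=False)
            manifest.mark("evaluate")
        artefacts["evaluate"] = table

    if "pair_evaluate" in stages and designed is not None:
        # reverse partner from the planted universal site
        universal_rev = primers.Primer(
            name="UNIV-R",
            residues=revcomp(truth.window_motifs[1]),
            target=config.target_clade,
            role="reverse",
        )
        table = primers.specificity_table(
            [(designed, universal_rev)], database, min_amplicon=config.min_amplicon
        )
        if not manifest.done("pair_evaluate"):
            table.to_csv(out / "pair_specificity.tsv", sep="\t", index=False)
            manifest.mark("pair_evaluate")
        artefacts["pair_evaluate"] = table

    return artefacts
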