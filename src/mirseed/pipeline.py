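"""End-to-end orchestration of the analysis stages.

``run_all`` executes the stages in study order — preprocess, ncRNA
subtraction, conserved identification with the abundance filter, novel
candidate extraction, conservation scoring, cross-kingdom comparison — and
writes every report table into a run directory.  A run is fully determined
by its configuration (plus the simulation seed when reads are simulated),
so re-running a recorded config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate as annotate_mod
from . import conservation as conservation_mod
from . import mircompare as mircompare_mod
from . import simulate as simulate_mod
from .annotate import AnnotationParams, annotations_to_frame, family_summary
from .core_io import StageCounts, load_reference, read_fastq, write_fastq, write_reference
from .errors import ConfigError, PipelineError
from .mircompare import CompareParams
from .preprocess import PreprocessParams, collapse, run_preprocess, write_tags

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run.

    Either ``reads`` (a FASTQ path, with reference FASTA paths) or
    ``simulation`` (generate the library first) must be provided.
    """

    output_dir: str = "run"
    reads: str | None = None
    plant_reference: str | None = None
    ncrna_reference: str | None = None
    animal_reference: str | None = None
    simulation: simulate_mod.SimulationConfig | None = None
    preprocess: PreprocessParams | None = None
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    compare: CompareParams = field(default_factory=CompareParams)
    conservation_mode: str = "exact_equal"
    species_prefix: str = "mol"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {k: encode(v) for k, v in obj.items()}
            return obj

        return encode(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if data.get("simulation") is not None:
            sim = dict(data["simulation"])
            for key in ("members_per_family", "mature_length_range",
                        "ncrna_length_range", "fragment_length_range",
                        "animal_mimic_distances"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            if sim.get("length_weights"):
                sim["length_weights"] = {int(k): float(v)
                                         for k, v in sim["length_weights"].items()}
            data["simulation"] = simulate_mod.SimulationConfig(**sim)
        if data.get("preprocess") is not None:
            data["preprocess"] = PreprocessParams(**data["preprocess"])
        if data.get("compare") is not None:
            comp = dict(data["compare"])
            if "seed_window" in comp:
                comp["seed_window"] = tuple(comp["seed_window"])
            data["compare"] = CompareParams(**comp)
        if data.get("annotation") is not None:
            data["annotation"] = AnnotationParams(**data["annotation"])
        return cls(**data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


@dataclass
class RunResult:
    """Everything a completed run produced, plus where it was written."""

    output_dir: Path
    stage_counts: StageCounts
    bins: annotate_mod.AnnotationBins
    conservation: list
    comparisons: list
    manifest: simulate_mod.TruthManifest | None = None


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline per the configuration.

    Any stage failure aborts with :class:`PipelineError` naming the stage,
    after writing a partial-run manifest listing the stages completed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    completed: list[str] = []
    manifest = None

    def checkpoint(stage: str) -> None:
        completed.append(stage)
        (out / "run_manifest.json").write_text(
            json.dumps({"completed_stages": completed}, indent=2) + "\n")

    try:
        stage = "inputs"
        if config.simulation is not None:
            refs = simulate_mod.build_references(config.simulation)
            reads, manifest = simulate_mod.simulate_library(config.simulation, refs)
            write_fastq(reads, out / "reads.fastq", alphabet="DNA")
            manifest.write(out / "truth_manifest.tsv")
            write_reference(refs.plant, out / "plant_reference.fasta")
            write_reference(refs.ncrna, out / "ncrna_reference.fasta")
            write_reference(refs.animal, out / "animal_reference.fasta")
            plant_ref, ncrna_ref, animal_ref = refs.plant, refs.ncrna, refs.animal
            preprocess_params = config.preprocess or PreprocessParams(
                adapter=config.simulation.adapter)
        else:
            if not (config.reads and config.plant_reference and config.ncrna_reference):
                raise ConfigError("reads, plant_reference and ncrna_reference "
                                  "paths are required without simulation")
            if config.preprocess is None:
                raise ConfigError("preprocess parameters (adapter) are required "
                                  "for file inputs")
            reads = list(read_fastq(config.reads))
            plant_ref = load_reference(config.plant_reference)
            ncrna_ref = load_reference(config.ncrna_reference,
                                       default_class="other_ncRNA",
                                       default_species="ref")
            animal_ref = (load_reference(config.animal_reference)
                          if config.animal_reference else [])
            preprocess_params = config.preprocess
        checkpoint(stage)

        stage = "preprocess"
        clean_reads, counts = run_preprocess(reads, preprocess_params)
        tags = collapse(clean_reads)
        counts.add("collapse_reads", len(clean_reads), len(clean_reads))
        write_tags(tags, out / "tags.tsv")
        checkpoint(stage)

        stage = "annotate"
        bins, ann_counts = annotate_mod.annotate_tags(
            tags, ncrna_ref, plant_ref, config.annotation,
            species_prefix=config.species_prefix)
        counts.extend(ann_counts)
        annotations_to_frame(bins.conserved).to_csv(
            out / "annotations.tsv", sep="\t", index=False)
        import pandas as pd

        pd.DataFrame([(s.family, s.n_members, s.total_count)
                      for s in family_summary(bins.conserved)],
                     columns=["family", "n_members", "total_count"]).to_csv(
            out / "family_summary.tsv", sep="\t", index=False)
        annotate_mod.write_candidates_fasta(bins.candidate, out / "candidates.fasta")
        dist = annotate_mod.length_distribution(
            [t for t in tags], weighting="by_read")
        dist.rename_axis("length").rename("proportion").to_csv(
            out / "length_distribution.tsv", sep="\t")
        checkpoint(stage)

        stage = "conservation"
        profile = conservation_mod.conservation_profile(
            bins.conserved, plant_ref, mode=config.conservation_mode,
            query_species=config.species_prefix)
        conservation_mod.results_to_frame(profile).to_csv(
            out / "conservation.tsv", sep="\t", index=False)
        checkpoint(stage)

        stage = "mircompare"
        comparisons = []
        if animal_ref:
            focal_entries = [e for e in plant_ref
                             if e.species_code == config.species_prefix]
            comparisons = mircompare_mod.compare_libraries(
                focal_entries, animal_ref, config.compare)
            mircompare_mod.results_to_frame(comparisons).to_csv(
                out / "comparison.tsv", sep="\t", index=False)
        checkpoint(stage)

        stage = "reports"
        counts.write(out / "stage_counts.tsv")
        checkpoint(stage)
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    return RunResult(output_dir=out, stage_counts=counts, bins=bins,
                     conservation=profile, comparisons=comparisons,
                     manifest=manifest)


def report_stage_counts(result: RunResult):
    """Stage-count cascade of a run as a DataFrame (one row per stage)."""
    return result.stage_counts.to_frame()
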