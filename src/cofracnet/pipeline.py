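"""End-to-end orchestration of the comparative clustering workflow.

Stages, in order: per-dataset Pearson correlation (skipped for precomputed
score-matrix inputs) -> interactor ranking and orthology-aware RBO between
every dataset pair -> reciprocal top-hit selection -> per-pair mean
normalization -> hypernetwork assembly -> Markov clustering -> subcluster
splitting, FrC scoring, coherence, filtering, best-guess selection and
optional reference annotation -> optional reference-based evaluation (MMR).

Feeding the correlation matrix of a profile dataset back in as a
score-matrix input reproduces the profile-path results exactly (two-path
equivalence).
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import io as _io
from .evaluate import MatchingResult, maximum_matching_ratio, process_reference_set
from .mcl import MCLParams, run_mcl
from .network import (
    build_hypernetwork,
    normalize_pair_scores,
    pairwise_interactor_similarity,
    select_reciprocal_top_hits,
)
from .postprocess import EquivalenceIndex, postprocess_clusters
from .scoring import RBOParams, correlation_matrix
from .types import (
    Collection,
    HyperNetwork,
    InteractionMatrix,
    OrthologyMap,
    ProfileDataset,
    ReferenceComplexSet,
    SuperCluster,
    ValidationError,
)

logger = logging.getLogger("cofracnet")

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline",
           "run_pipeline_files"]


@dataclass
class PipelineParams:
    """All tunable workflow parameters, with the tool defaults."""

    rbo_p: float = 0.9
    rbo_coverage: float = 0.99
    top_hit_fraction: float = 0.01
    inflation: float = 2.0
    min_matches: int = 2
    min_frc: float = 0.5
    best_guess_threshold: float = 0.5
    annotation_threshold: float = 0.5
    mmr_min_overlap: float = 0.25
    #: evaluate MMR on best-guess member sets instead of all clustered
    mmr_best_guess_only: bool = False

    def rbo(self) -> RBOParams:
        return RBOParams(p=self.rbo_p, coverage=self.rbo_coverage)

    def mcl(self) -> MCLParams:
        return MCLParams(inflation=self.inflation)


@dataclass
class PipelineResult:
    superclusters: list[SuperCluster]
    network: HyperNetwork
    collections: dict[str, Collection]
    equivalence: EquivalenceIndex
    params: dict = field(default_factory=dict)
    evaluation: MatchingResult | None = None


def _as_matrix(d: ProfileDataset | InteractionMatrix) -> InteractionMatrix:
    if isinstance(d, InteractionMatrix):
        return d
    return correlation_matrix(d)


def _build_equivalence(matrices: list[InteractionMatrix],
                       collections: dict[str, Collection],
                       orthologies: list[OrthologyMap]) -> EquivalenceIndex:
    return EquivalenceIndex(
        dataset_species={m.dataset_id: m.species_id for m in matrices},
        dataset_collection={m.dataset_id: m.collection_id for m in matrices},
        collection_species={c.collection_id: c.species_id
                            for c in collections.values()},
        orthologies=orthologies,
    )


def run_pipeline(inputs: list[ProfileDataset | InteractionMatrix],
                 collections: dict[str, Collection],
                 orthologies: list[OrthologyMap],
                 params: PipelineParams | None = None,
                 reference: ReferenceComplexSet | None = None,
                 reference_collection: str | None = None,
                 ) -> PipelineResult:
    """Run the full workflow on in-memory inputs.

    Fails fast if any cross-species dataset pair lacks an orthology map.
    Deterministic given inputs (no stage is stochastic).
    """
    params = params or PipelineParams()
    if not inputs:
        raise ValidationError("no input datasets")
    matrices = [_as_matrix(d) for d in inputs]
    equiv = _build_equivalence(matrices, collections, orthologies)

    species = sorted({m.species_id for m in matrices})
    for sa, sb in itertools.combinations(species, 2):
        if not equiv.has_pair(sa, sb):
            raise ValidationError(
                f"missing orthology for species pair ({sa}, {sb})"
            )

    logger.info("comparing %d datasets pairwise", len(matrices))
    edge_sets = []
    for ma, mb in itertools.combinations(matrices, 2):
        # mapping translates B identifiers into A's namespace
        mapping = equiv.directed_map(mb.species_id, ma.species_id)
        table = pairwise_interactor_similarity(ma, mb, mapping, params.rbo())
        es = select_reciprocal_top_hits(table, params.top_hit_fraction)
        logger.info("%s vs %s: %d reciprocal top hits",
                    ma.dataset_id, mb.dataset_id, len(es.edges))
        edge_sets.append(es)

    edge_sets = normalize_pair_scores(edge_sets)
    all_elements = [(m.dataset_id, p) for m in matrices for p in m.proteins]
    net = build_hypernetwork(edge_sets, all_elements)
    logger.info("hypernetwork: %d nodes, %d edges (%d isolated elements)",
                net.n_nodes, net.n_edges, len(net.isolated))

    raw_clusters = run_mcl(net, params.mcl())
    logger.info("MCL produced %d raw clusters", len(raw_clusters))

    supers = postprocess_clusters(
        raw_clusters, collections, equiv,
        best_guess_threshold=params.best_guess_threshold,
        min_matches=params.min_matches, min_frc=params.min_frc,
        reference=reference, reference_collection=reference_collection,
        annotation_threshold=params.annotation_threshold,
    )

    evaluation = None
    if reference is not None and reference_collection is not None:
        coll = collections[reference_collection]
        detection: dict[str, int] = {}
        for m in matrices:
            if m.collection_id == reference_collection:
                for p in m.proteins:
                    detection[p] = detection.get(p, 0) + 1
        processed = process_reference_set(reference, detection)
        cluster_sets = []
        for sc in supers:
            if not sc.passed_filter:
                continue
            sub = sc.subclusters.get(reference_collection)
            if sub is None:
                continue
            members = (set(sub.best_guess) if params.mmr_best_guess_only
                       else set(sub.members))
            if members:
                cluster_sets.append(members)
        evaluation = maximum_matching_ratio(
            cluster_sets, processed, min_overlap=params.mmr_min_overlap)
        logger.info("MMR against %d processed reference complexes: %.4f",
                    len(processed), evaluation.mmr)
        _ = coll  # reference collection validated above

    return PipelineResult(supers, net, collections, equiv,
                          params=asdict(params), evaluation=evaluation)


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline_files(sample_sheet, ortho_dir=None,
                       params: PipelineParams | None = None,
                       reference_path=None, reference_collection=None,
                       out_dir=None) -> PipelineResult:
    """File-level entry point: load inputs, run, optionally write tables.

    Orthology files are looked up in ``ortho_dir`` as ``{spA}-{spB}.tsv``
    (either species order). A run log recording every parameter and input
    checksum is written alongside the output tables.
    """
    params = params or PipelineParams()
    records, collections = _io.load_sample_sheet(sample_sheet)
    inputs: list[ProfileDataset | InteractionMatrix] = []
    checksums = {str(sample_sheet): _checksum(sample_sheet)}
    for rec in records:
        checksums[str(rec["path"])] = _checksum(rec["path"])
        loader = (_io.load_profile_dataset if rec["type"] == "profile"
                  else _io.load_score_matrix)
        inputs.append(loader(rec["path"], rec["dataset_id"],
                             rec["collection_id"], rec["species_id"]))

    species = sorted({r["species_id"] for r in records})
    orthologies: list[OrthologyMap] = []
    for sa, sb in itertools.combinations(species, 2):
        if ortho_dir is None:
            raise ValidationError(
                f"multiple species present but no orthology directory given "
                f"(need ({sa}, {sb}))"
            )
        cand = [Path(ortho_dir) / f"{sa}-{sb}.tsv",
                Path(ortho_dir) / f"{sb}-{sa}.tsv"]
        hit = next((c for c in cand if c.exists()), None)
        if hit is None:
            raise ValidationError(
                f"missing orthology file for species pair ({sa}, {sb}); "
                f"looked for {[str(c) for c in cand]}"
            )
        checksums[str(hit)] = _checksum(hit)
        first = sa if hit.name.startswith(sa) else sb
        second = sb if first == sa else sa
        orthologies.append(_io.load_orthology(hit, first, second))

    reference = None
    if reference_path is not None:
        checksums[str(reference_path)] = _checksum(reference_path)
        reference = _io.load_reference_complexes(reference_path)

    result = run_pipeline(inputs, collections, orthologies, params,
                          reference=reference,
                          reference_collection=reference_collection)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_cluster_tables(result.superclusters, result.network, out)
        with open(out / "run_log.txt", "w", encoding="utf-8") as fh:
            fh.write("# parameters\n")
            for k, v in sorted(result.params.items()):
                fh.write(f"{k}\t{v}\n")
            fh.write("# input checksums (sha256/16)\n")
            for path, cs in sorted(checksums.items()):
                fh.write(f"{cs}\t{path}\n")
            if result.evaluation is not None:
                fh.write(f"# MMR\t{result.evaluation.mmr:.6f}\n")
    return result
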