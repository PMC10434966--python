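"""Synthetic multi-species complexome-profiling data with planted complexes.

The generator emulates the shape of real co-fractionation studies: several
species, each with one or more collections of replicate datasets, proteins
migrating as Gaussian abundance peaks across fractions. Members of a planted
complex share one peak position within a species (co-migration), with the
peak centre jittered per dataset and multiplicative log-normal noise per
measurement; background proteins get independent random peaks redrawn per
dataset so they do not reproducibly co-migrate. A configurable share of each
complex's subunits is species-specific; the remaining conserved subunits are
paired across species in the emitted orthology maps, minus a dropout
probability emulating incomplete orthology prediction. Background proteins
carry no orthology records.

Complex migration positions are evenly spaced along the gradient (with small
random offsets, independently permuted per species) so that planted
complexes are resolvable in principle — two complexes co-migrating exactly
would be inherently indistinguishable to any co-fractionation method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_orthology, write_profile_dataset
from .types import Collection, OrthologyMap, ProfileDataset, ValidationError

__all__ = ["SimConfig", "GroundTruth", "generate_collections",
           "write_simulation"]


@dataclass
class SimConfig:
    """World description for the synthetic complexome generator.

    Defaults describe a two-species desk-scale benchmark: 2 species x 1
    collection x 2 replicate datasets, 60 fractions, 10 planted complexes of
    5-10 subunits, 10% relative abundance noise, peak jitter of at most one
    fraction between replicates.
    """

    n_species: int = 2
    collections_per_species: int = 1
    datasets_per_collection: int = 2
    n_fractions: int = 60
    n_complexes: int = 10
    complex_size_range: tuple[int, int] = (5, 10)
    #: share of each complex's subunits present in only one species
    taxon_specific_fraction: float = 0.2
    #: probability a conserved subunit pair lacks an orthology record
    ortholog_dropout: float = 0.1
    #: realistic proteome scale: the top-1% reciprocal cutoff is only
    #: meaningful when ceil(0.01 * proteome) is at least a complex's size
    background_proteins: int = 1000
    peak_width: float = 2.0
    #: max per-dataset shift of a complex's peak centre, in fractions
    peak_jitter: float = 1.0
    #: sd of the log-normal multiplicative abundance noise
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("taxon_specific_fraction", "ortholog_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        lo, hi = self.complex_size_range
        if not 2 <= lo <= hi:
            raise ValidationError("complex sizes must be >= 2 and ordered")
        if min(self.n_species, self.collections_per_species,
               self.datasets_per_collection, self.n_fractions,
               self.n_complexes) < 1:
            raise ValidationError("counts must be positive")
        if self.noise_sd < 0 or self.peak_width <= 0:
            raise ValidationError("noise_sd >= 0 and peak_width > 0 required")


@dataclass
class GroundTruth:
    """Planted structure behind a simulated study.

    complexes : species -> complex id -> that species' full member set
        (conserved plus species-specific subunits).
    specific : species -> complex id -> the species-specific subset.
    orthology : species pair -> true conserved-subunit pairings (before
        dropout; the emitted maps are a subset of these).
    """

    complexes: dict[str, dict[str, set[str]]]
    specific: dict[str, dict[str, set[str]]]
    orthology: dict[tuple[str, str], set[tuple[str, str]]] = field(
        default_factory=dict)


def _gaussian(frac: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((frac - centre) / width) ** 2)


def generate_collections(cfg: SimConfig,
                         ) -> tuple[list[ProfileDataset],
                                    list[OrthologyMap],
                                    GroundTruth,
                                    dict[str, Collection]]:
    """Generate profile datasets, orthology maps and the ground truth.

    Fully reproducible from ``cfg.seed``. Returns the datasets (one per
    species x collection x replicate), the emitted pairwise orthology maps,
    the planted ground truth, and the collection table.
    """
    rng = np.random.default_rng(cfg.seed)
    margin = 3.0 * cfg.peak_width + cfg.peak_jitter + 1.0
    # planted complexes must be resolvable: adjacent migration positions at
    # least ~2 peak widths apart, or no co-fractionation method could
    # distinguish them even in principle
    span = cfg.n_fractions - 2 * margin
    if cfg.n_complexes > 1:
        spacing = span / (cfg.n_complexes - 1)
        if spacing < 1.9 * cfg.peak_width:
            raise ValidationError(
                f"{cfg.n_complexes} complexes over {cfg.n_fractions} "
                f"fractions at peak width {cfg.peak_width} cannot be "
                f"separated by >=2 peak widths"
            )
    if span <= 0:
        raise ValidationError(
            f"n_fractions={cfg.n_fractions} too small for peak width "
            f"{cfg.peak_width}"
        )

    species = [f"sp{i + 1}" for i in range(cfg.n_species)]
    lo, hi = cfg.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_complexes)
    n_specific = [int(np.floor(cfg.taxon_specific_fraction * s))
                  for s in sizes]
    complex_ids = [f"cplx{c + 1:02d}" for c in range(cfg.n_complexes)]

    # membership: conserved core shared across species, plus per-species
    # specific subunits; identifiers are namespaced per species
    complexes: dict[str, dict[str, set[str]]] = {s: {} for s in species}
    specific: dict[str, dict[str, set[str]]] = {s: {} for s in species}
    conserved_index: dict[str, list[str]] = {}  # cid -> subunit tags
    for cid, size, nspec in zip(complex_ids, sizes, n_specific):
        core = [f"{cid}s{k + 1:02d}" for k in range(size - nspec)]
        conserved_index[cid] = core
        for s in species:
            own = {f"{s}_{tag}" for tag in core}
            spec = {f"{s}_{cid}x{k + 1:02d}" for k in range(nspec)}
            complexes[s][cid] = own | spec
            specific[s][cid] = spec

    # evenly spaced migration positions, independently permuted per species
    base = np.linspace(margin, cfg.n_fractions - margin, cfg.n_complexes)
    centres: dict[str, dict[str, float]] = {}
    for s in species:
        order = rng.permutation(cfg.n_complexes)
        offsets = rng.uniform(-0.5, 0.5, cfg.n_complexes)
        centres[s] = {
            complex_ids[c]: float(base[order[c]] + offsets[c])
            for c in range(cfg.n_complexes)
        }

    # per-(species, protein) amplitude, constant across replicates
    amplitude: dict[tuple[str, str], float] = {}

    def amp(s: str, prot: str) -> float:
        key = (s, prot)
        if key not in amplitude:
            amplitude[key] = float(100.0 * rng.lognormal(0.0, 0.25))
        return amplitude[key]

    frac = np.arange(cfg.n_fractions, dtype=float)
    datasets: list[ProfileDataset] = []
    collections: dict[str, Collection] = {}
    for s in species:
        bg = [f"{s}_bg{k + 1:03d}" for k in range(cfg.background_proteins)]
        proteins = sorted(
            {p for members in complexes[s].values() for p in members}
        ) + bg
        prot_complex = {
            p: cid for cid, members in complexes[s].items() for p in members
        }
        for c in range(cfg.collections_per_species):
            coll_id = f"{s}_c{c + 1}"
            ds_ids = []
            for r in range(cfg.datasets_per_collection):
                ds_id = f"{coll_id}_r{r + 1}"
                ds_ids.append(ds_id)
                jit = {
                    cid: float(rng.uniform(-cfg.peak_jitter, cfg.peak_jitter))
                    for cid in complex_ids
                }
                rows = np.empty((len(proteins), cfg.n_fractions))
                for i, p in enumerate(proteins):
                    cid = prot_complex.get(p)
                    if cid is not None:
                        centre = centres[s][cid] + jit[cid]
                        width = cfg.peak_width
                    else:
                        # background: independent random peak per dataset,
                        # with heterogeneous width (monomers and smears do
                        # not share the sharp co-migration peak of an
                        # assembled complex)
                        centre = float(rng.uniform(margin,
                                                   cfg.n_fractions - margin))
                        width = float(cfg.peak_width
                                      * rng.uniform(0.75, 2.5))
                    shape = _gaussian(frac, centre, width)
                    if cfg.noise_sd > 0:
                        noise = np.exp(rng.normal(0.0, cfg.noise_sd,
                                                  cfg.n_fractions))
                    else:
                        noise = 1.0
                    rows[i] = amp(s, p) * shape * noise
                datasets.append(
                    ProfileDataset(ds_id, coll_id, s, list(proteins), rows)
                )
            collections[coll_id] = Collection(coll_id, s, ds_ids)

    truth = GroundTruth(complexes, specific)
    orthologies: list[OrthologyMap] = []
    for i, sa in enumerate(species):
        for sb in species[i + 1:]:
            true_pairs = {
                (f"{sa}_{tag}", f"{sb}_{tag}")
                for cid in complex_ids
                for tag in conserved_index[cid]
            }
            truth.orthology[(sa, sb)] = true_pairs
            emitted = {
                pair for pair in sorted(true_pairs)
                if rng.random() >= cfg.ortholog_dropout
            }
            orthologies.append(OrthologyMap((sa, sb), emitted))
    return datasets, orthologies, truth, collections


def write_simulation(cfg: SimConfig, out_dir) -> Path:
    """Write a simulated study as pipeline-ready TSVs; returns the sample
    sheet path. Also writes a ground-truth member table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    datasets, orthologies, truth, _ = generate_collections(cfg)
    rows = ["dataset_id\tcollection_id\tspecies_id\tpath\ttype"]
    for ds in datasets:
        fname = f"{ds.dataset_id}.tsv"
        write_profile_dataset(ds, out / fname)
        rows.append(f"{ds.dataset_id}\t{ds.collection_id}\t{ds.species_id}"
                    f"\t{fname}\tprofile")
    sheet = out / "samples.tsv"
    sheet.write_text("\n".join(rows) + "\n", encoding="utf-8")
    for om in orthologies:
        a, b = om.species_pair
        write_orthology(om, out / f"{a}-{b}.tsv")
    with open(out / "ground_truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("species\tcomplex\tprotein\tspecies_specific\n")
        for s in sorted(truth.complexes):
            for cid in sorted(truth.complexes[s]):
                for p in sorted(truth.complexes[s][cid]):
                    flag = int(p in truth.specific[s][cid])
                    fh.write(f"{s}\t{cid}\t{p}\t{flag}\n")
    return sheet
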