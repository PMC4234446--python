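"""Seeded generators for motif-TF databases with planted ground truth.

The generator emulates the statistical structure of an annotated motif-TF
repository searched against a target proteome:

* TF families share a characteristic binding motif; each member carries a
  noisy variant of it (columns drawn around the family consensus).
* Families come in *sister pairs* descended from a common ancestral
  consensus and differing at a few positions - mirroring the superfamily
  structure of real regulators, where e.g. G-box and E-box binders, or
  several AC-rich element binders, recognise closely related sequences.
* Family members share a conserved DNA-binding domain (DBD) embedded in
  random flanks; a fraction of DBD positions is annotated as the
  DNA-contacting interface.
* The target proteome holds, for every database TF, one planted homolog of
  the same DBD lineage plus unrelated decoy proteins.

"Discovered" motif queries are assembled the way de-novo motif discovery
on co-regulated promoters produces them: from a handful of sampled sites,
some misaligned by one position and some contaminated by sites of the
sister family.  Individual site queries are the clean sites themselves.

All randomness flows from the single integer seed in the configuration;
no global random state is touched.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .motif_model import (BASES, NucleotideMotif, motif_from_sequences,
                          write_motifs)
from .promoter_screen import Condition, ExpressionMatrix, PromoterRecord
from .structure_interface import InterfaceAnnotation
from .tf_prediction import MotifTFDatabase, Proteome, TFRecord

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a small but realistic screen: 5 TF families of 4
    members each, 60-residue DBDs diverging at 10% of sites, sharp
    10-column motifs, 1,000-bp promoters and 2-10-fold induction of
    up-regulated genes.
    """

    seed: int = 0
    n_families: int = 5
    members_per_family: int = 4
    dbd_length: int = 60
    dbd_divergence: float = 0.1
    interface_fraction: float = 0.25
    motif_width: int = 10
    motif_info: float = 50.0
    member_concentration: float = 50.0
    flank_length: int = 40
    n_decoy_proteins: int | None = None  # default: one per database TF
    sister_divergence: int = 2  # consensus positions changed in a sister
    n_promoters: int = 50
    promoter_length: int = 1000
    planted_fraction: float = 0.5
    n_conditions: int = 10
    drought_conditions: int = 3
    fold_range: tuple[float, float] = (2.0, 10.0)

    def __post_init__(self):
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValidationError("need at least one family and one member")
        if not (0.0 <= self.dbd_divergence <= 1.0
                and 0.0 <= self.planted_fraction <= 1.0
                and 0.0 <= self.interface_fraction <= 1.0):
            raise ValidationError("probabilities must lie in [0, 1]")
        if not (5 <= self.motif_width <= 10):
            raise ValidationError("motif width must lie in [5, 10]")


@dataclass
class PlantedTruth:
    """What a successful analysis should recover."""

    family_motifs: dict[str, NucleotideMotif] = field(default_factory=dict)
    motif_family: dict[str, str] = field(default_factory=dict)
    tf_family: dict[str, str] = field(default_factory=dict)
    homolog_of: dict[str, str] = field(default_factory=dict)  # tf -> protein
    family_homologs: dict[str, list[str]] = field(default_factory=dict)
    sister: dict[str, str | None] = field(default_factory=dict)
    site_positions: dict[str, int] = field(default_factory=dict)
    drought_up: frozenset = frozenset()

    def to_json(self) -> str:
        return json.dumps({
            "motif_family": self.motif_family,
            "tf_family": self.tf_family,
            "homolog_of": self.homolog_of,
            "family_homologs": self.family_homologs,
            "sister": self.sister,
            "site_positions": self.site_positions,
            "drought_up": sorted(self.drought_up),
        }, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Low-level sampling
# ---------------------------------------------------------------------------

def _sharp_columns(dominant: np.ndarray, info: float,
                   rng: np.random.Generator) -> np.ndarray:
    cols = []
    for b in dominant:
        alpha = np.full(4, 0.5)
        alpha[b] = info
        cols.append(rng.dirichlet(alpha))
    return np.array(cols)


def _member_variant(freqs: np.ndarray, concentration: float,
                    rng: np.random.Generator) -> np.ndarray:
    return np.array([rng.dirichlet(row * concentration + 0.1)
                     for row in freqs])


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in _AA20 if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def sample_site(motif: NucleotideMotif, rng: np.random.Generator) -> str:
    """One site sequence drawn column-wise from a motif's frequencies."""
    pwm = motif.counts / motif.counts.sum(axis=1, keepdims=True)
    return "".join(BASES[rng.choice(4, p=row)] for row in pwm)


# ---------------------------------------------------------------------------
# Database + proteome
# ---------------------------------------------------------------------------

def generate_database(cfg: SynthConfig
                      ) -> tuple[MotifTFDatabase, Proteome, PlantedTruth]:
    """A motif-TF database, a target proteome and the planted truth."""
    rng = np.random.default_rng([cfg.seed, 0])
    truth = PlantedTruth()
    motifs, tfs = [], []
    proteome_entries: dict[str, tuple[str, str]] = {}

    n_iface = max(1, int(round(cfg.interface_fraction * cfg.dbd_length)))
    dominants: list[np.ndarray] = []
    family_names = [f"fam{i + 1}" for i in range(cfg.n_families)]
    for fi, fam in enumerate(family_names):
        if fi % 2 == 1:
            # sister family: ancestral consensus with a few changed positions
            dom = dominants[fi - 1].copy()
            changed = rng.choice(cfg.motif_width,
                                 size=min(cfg.sister_divergence,
                                          cfg.motif_width), replace=False)
            for pos in changed:
                alts = [b for b in range(4) if b != dom[pos]]
                dom[pos] = alts[rng.integers(3)]
            truth.sister[fam] = family_names[fi - 1]
            truth.sister[family_names[fi - 1]] = fam
        else:
            dom = rng.integers(0, 4, size=cfg.motif_width)
            truth.sister.setdefault(fam, None)
        dominants.append(dom)

        fam_freqs = _sharp_columns(dom, cfg.motif_info, rng)
        truth.family_motifs[fam] = NucleotideMotif(
            id=f"{fam}_consensus", counts=fam_freqs, nsites=20)
        fam_dbd = _random_protein(cfg.dbd_length, rng)
        iface_rel = np.sort(rng.choice(cfg.dbd_length, size=n_iface,
                                       replace=False))
        truth.family_homologs[fam] = []
        for mi in range(cfg.members_per_family):
            tf_id = f"{fam}_tf{mi + 1}"
            motif_id = f"{fam}_m{mi + 1}"
            member_freqs = _member_variant(fam_freqs,
                                           cfg.member_concentration, rng)
            motifs.append(NucleotideMotif(id=motif_id, counts=member_freqs,
                                          nsites=20))
            member_dbd = _mutate(fam_dbd, cfg.dbd_divergence, rng)
            protein = (_random_protein(cfg.flank_length, rng) + member_dbd
                       + _random_protein(cfg.flank_length, rng))
            iface = InterfaceAnnotation(
                tf_id=tf_id,
                positions=tuple(int(p) + cfg.flank_length
                                for p in iface_rel))
            tfs.append(TFRecord(tf_id=tf_id, name=tf_id, family=fam,
                                species="synthetic", protein_seq=protein,
                                motif_ids=[motif_id], interface=iface))
            truth.motif_family[motif_id] = fam
            truth.tf_family[tf_id] = fam

            hom_id = f"HOM_{tf_id}"
            hom_dbd = _mutate(member_dbd, cfg.dbd_divergence, rng)
            hom_seq = (_random_protein(cfg.flank_length, rng) + hom_dbd
                       + _random_protein(cfg.flank_length, rng))
            proteome_entries[hom_id] = (f"planted homolog of {tf_id}",
                                        hom_seq)
            truth.homolog_of[tf_id] = hom_id
            truth.family_homologs[fam].append(hom_id)

    n_decoys = (cfg.n_decoy_proteins if cfg.n_decoy_proteins is not None
                else len(tfs))
    total_len = 2 * cfg.flank_length + cfg.dbd_length
    for di in range(n_decoys):
        pid = f"DECOY_{di + 1}"
        proteome_entries[pid] = ("unrelated protein",
                                 _random_protein(total_len, rng))

    db = MotifTFDatabase(motifs=motifs, tfs=tfs)
    return db, Proteome(entries=proteome_entries), truth


# ---------------------------------------------------------------------------
# Query construction (per-site and discovered-motif modes)
# ---------------------------------------------------------------------------

def site_queries(cfg: SynthConfig, truth: PlantedTruth, family: str,
                 n_sites: int = 4) -> list[NucleotideMotif]:
    """Clean individual cis-site queries sampled from a family motif."""
    rng = np.random.default_rng([cfg.seed, 1, zlib.crc32(family.encode())])
    fam_motif = truth.family_motifs[family]
    out = []
    for i in range(n_sites):
        site = sample_site(fam_motif, rng)
        out.append(motif_from_sequences([site], id=f"{family}_site{i + 1}"))
    return out


def discovered_motif(cfg: SynthConfig, truth: PlantedTruth, family: str,
                     n_sites: int = 4, n_contaminant: int = 2,
                     jitter_prob: float = 0.25) -> NucleotideMotif:
    """A de-novo-discovery-style motif query for one family.

    Built from ``n_sites`` sites of the family plus ``n_contaminant`` sites
    of its sister family (or a random other family when it has no sister),
    each site shifted by one position with probability ``jitter_prob`` -
    the chimerism and misalignment that blur real discovered matrices.
    """
    rng = np.random.default_rng([cfg.seed, 2, zlib.crc32(family.encode())])
    fam_motif = truth.family_motifs[family]
    other = truth.sister.get(family)
    if other is None:
        candidates = [f for f in truth.family_motifs if f != family]
        other = candidates[rng.integers(len(candidates))] if candidates \
            else family
    sites = [sample_site(fam_motif, rng) for _ in range(n_sites)]
    sites += [sample_site(truth.family_motifs[other], rng)
              for _ in range(n_contaminant)]
    width = fam_motif.width
    jittered = []
    for s in sites:
        if rng.random() < jitter_prob:
            shift = 1 if rng.random() < 0.5 else -1
            pad = "".join(rng.choice(list(BASES), size=1))
            s = (pad + s[:-1]) if shift > 0 else (s[1:] + pad)
        jittered.append(s[:width])
    return motif_from_sequences(jittered, id=f"{family}_discovered")


# ---------------------------------------------------------------------------
# Promoters and expression
# ---------------------------------------------------------------------------

def generate_promoter_set(cfg: SynthConfig, motif: NucleotideMotif
                          ) -> tuple[list[PromoterRecord], PlantedTruth]:
    """Uniform-background promoters with sites planted from a motif."""
    if motif.width > cfg.promoter_length:
        raise ValidationError("motif wider than promoter")
    rng = np.random.default_rng([cfg.seed, 3])
    truth = PlantedTruth()
    promoters = []
    n_planted = int(round(cfg.planted_fraction * cfg.n_promoters))
    for i in range(cfg.n_promoters):
        gene = f"g{i + 1:04d}"
        seq = list(rng.choice(list(BASES), size=cfg.promoter_length))
        if i < n_planted:
            site = sample_site(motif, rng)
            pos = int(rng.integers(0, cfg.promoter_length - motif.width + 1))
            seq[pos:pos + motif.width] = list(site)
            truth.site_positions[gene] = pos
        promoters.append(PromoterRecord(gene_id=gene, sequence="".join(seq)))
    truth.drought_up = frozenset(truth.site_positions)
    return promoters, truth


def generate_expression_matrix(cfg: SynthConfig, gene_ids: list[str],
                               drought_up: set[str]) -> ExpressionMatrix:
    """Fold-change table with drought conditions inducing ``drought_up``.

    Drought-flagged conditions give the planted genes uniform fold changes
    in ``fold_range``; other genes sit log-normally around 1.  Non-drought
    conditions induce an independently drawn gene set of the same size.
    """
    if not gene_ids:
        raise ValidationError("empty gene list")
    extra = set(drought_up) - set(gene_ids)
    if extra:
        raise ValidationError(f"drought_up genes not in gene list: "
                              f"{sorted(extra)}")
    rng = np.random.default_rng([cfg.seed, 4])
    lo, hi = cfg.fold_range
    conditions = []
    columns = []
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for ci in range(cfg.n_conditions):
        is_drought = ci < cfg.drought_conditions
        cid = f"c{ci + 1:02d}"
        conditions.append(Condition(condition_id=cid,
                                    tissue="roots" if ci % 2 else "shoots",
                                    timepoint=f"{ci}h",
                                    is_drought=is_drought))
        if is_drought:
            up = drought_up
        else:
            up = set(rng.choice(gene_ids, size=min(len(drought_up),
                                                   len(gene_ids)),
                                replace=False))
        col = rng.lognormal(mean=0.0, sigma=0.2, size=len(gene_ids))
        for g in up:
            col[gene_index[g]] = rng.uniform(lo, hi)
        columns.append(col)
    return ExpressionMatrix(genes=list(gene_ids), conditions=conditions,
                            fold_change=np.array(columns).T)


# ---------------------------------------------------------------------------
# On-disk emission (the formats the rest of the package reads)
# ---------------------------------------------------------------------------

def write_dataset(outdir, db: MotifTFDatabase, proteome: Proteome,
                  truth: PlantedTruth) -> dict[str, Path]:
    """Write a generated dataset in the package's exchange formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "motifs": outdir / "motifs.meme",
        "tf_table": outdir / "tf_table.tsv",
        "tf_proteins": outdir / "tf_proteins.faa",
        "proteome": outdir / "proteome.faa",
        "interfaces": outdir / "interfaces.json",
        "truth": outdir / "truth.json",
    }
    write_motifs(db.motifs, paths["motifs"], "meme")
    with open(paths["tf_table"], "w") as fh:
        fh.write("tf_id\tname\tfamily\tspecies\tmotif_ids\n")
        for tf in db.tfs:
            fh.write(f"{tf.tf_id}\t{tf.name}\t{tf.family}\t{tf.species}\t"
                     + ";".join(tf.motif_ids) + "\n")
    with open(paths["tf_proteins"], "w") as fh:
        for tf in db.tfs:
            fh.write(f">{tf.tf_id} {tf.family}\n{tf.protein_seq}\n")
    with open(paths["proteome"], "w") as fh:
        for pid, (desc, seq) in proteome.entries.items():
            fh.write(f">{pid} {desc}\n{seq}\n")
    with open(paths["interfaces"], "w") as fh:
        json.dump({tf.tf_id: list(tf.interface.positions)
                   for tf in db.tfs if tf.interface is not None}, fh,
                  indent=1, sort_keys=True)
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths
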