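"""Synthetic bacterial species with a known ground-truth pan-genome.

A species is described by a set of gene families: *core* families carried by
every genome, *accessory* families carried by a configurable fraction of
genomes, and per-genome *unique* genes.  Every family has an ancestral
nucleotide sequence; each genome carries an independently mutated copy
(per-site substitutions at ``within_family_divergence``), so within-family
sequence identity stays far above, and between-family identity far below,
any clustering threshold of interest.  Genes are laid out in a fixed order
on a circular chromosome, separated by random intergenic spacers, which
makes the true family and coordinates of every gene known — the oracle that
downstream true/false-positive bookkeeping relies on.

Two closed forms used for validation: after mutating two copies of the same
ancestor independently at per-site rate ``d`` (substitution to one of the
other three bases, uniformly), the expected per-site identity is

    E[identity] = 1/4 + 3/4 * (1 - 4d/3)**2

and the genus partner (used as the inter-species contamination donor) is
produced by re-mutating every ancestor at ``genus_divergence`` before the
per-genome mutation, pushing partner-vs-resident identity well below the
lowest clustering threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, ParseError

# nucleotide codes: A=0 C=1 G=2 T=3 (complement is 3 - code)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

#: single-letter COG functional category codes
COG_LETTERS = tuple("ACDEFGHIJKLMNOPQRSTUVWXZ")


def encode_seq(seq: str) -> np.ndarray:
    """Nucleotide string -> uint8 code array (A=0, C=1, G=2, T=3)."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def decode_seq(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def revcomp(seq: str) -> str:
    return decode_seq(3 - encode_seq(seq)[::-1])


def expected_within_identity(divergence: float) -> float:
    """Expected per-site identity of two independently mutated family members."""
    lam = 1.0 - 4.0 * divergence / 3.0
    return 0.25 + 0.75 * lam * lam


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesModel:
    """Parameters defining a synthetic species and its gene-family inventory."""

    species_id: str = "species"
    n_core_families: int = 200
    n_accessory_families: int = 150
    accessory_prevalence_range: tuple[float, float] = (0.15, 0.85)
    unique_genes_per_genome: int = 15
    gene_length_range: tuple[int, int] = (300, 1500)
    intergenic_length_range: tuple[int, int] = (8000, 12000)
    within_family_divergence: float = 0.01
    genus_divergence: float = 0.30
    category_alphabet: tuple[str, ...] = COG_LETTERS
    max_si_threshold: float = 95.0
    rng_seed: int = 0


@dataclass(frozen=True)
class GeneFamilyAncestor:
    family_id: str
    ancestral_sequence: str
    category: str
    prevalence: float  # fraction of genomes carrying the family; 1.0 for core
    strand: str = "+"  # strand is a family property, fixed across genomes


@dataclass
class GeneAnnotation:
    """Ground-truth gene location; family_id is hidden from clustering."""

    gene_id: str
    family_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    category: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    genome_id: str
    sequence: str  # circular chromosome, forward strand
    annotations: list[GeneAnnotation] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene_sequence(self, ann: GeneAnnotation) -> str:
        """Gene-oriented sequence of an annotation (reverse-complemented for '-')."""
        raw = self.sequence[ann.start:ann.end]
        return revcomp(raw) if ann.strand == "-" else raw


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

_MODEL_FIELDS = set(SpeciesModel.__dataclass_fields__)


def build_species_model(config: dict) -> SpeciesModel:
    """Validate a parameter mapping and freeze it into a :class:`SpeciesModel`.

    Raises :class:`ConfigurationError` naming the offending field if counts
    are non-positive, ranges are out of order, or ``within_family_divergence``
    is too high for ``max_si_threshold`` (expected within-family identity must
    exceed the highest clustering threshold that will be applied).
    """
    unknown = set(config) - _MODEL_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown field(s): {sorted(unknown)}")
    cfg = dict(config)
    for key in ("accessory_prevalence_range", "gene_length_range",
                "intergenic_length_range", "category_alphabet"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    model = SpeciesModel(**cfg)

    if model.n_core_families < 1:
        raise ConfigurationError("n_core_families must be >= 1")
    if model.n_accessory_families < 0:
        raise ConfigurationError("n_accessory_families must be >= 0")
    if model.unique_genes_per_genome < 0:
        raise ConfigurationError("unique_genes_per_genome must be >= 0")
    lo, hi = model.accessory_prevalence_range
    if not (0.0 < lo <= hi < 1.0):
        raise ConfigurationError("accessory_prevalence_range must be ordered and in (0,1)")
    glo, ghi = model.gene_length_range
    if not (9 <= glo <= ghi) or glo % 3 or ghi % 3:
        raise ConfigurationError("gene_length_range must be ordered multiples of 3 (>= 9)")
    ilo, ihi = model.intergenic_length_range
    if not (1 <= ilo <= ihi):
        raise ConfigurationError("intergenic_length_range must be ordered and positive")
    if not (0.0 <= model.within_family_divergence < 0.75):
        raise ConfigurationError("within_family_divergence must be in [0, 0.75)")
    exp_ident = expected_within_identity(model.within_family_divergence)
    if exp_ident <= model.max_si_threshold / 100.0:
        raise ConfigurationError(
            "within_family_divergence too high: expected within-family identity "
            f"{exp_ident:.3f} does not exceed max_si_threshold {model.max_si_threshold}%"
        )
    if not (model.within_family_divergence <= model.genus_divergence < 0.75):
        raise ConfigurationError("genus_divergence must be in [within_family_divergence, 0.75)")
    if not model.category_alphabet or any(len(c) != 1 for c in model.category_alphabet):
        raise ConfigurationError("category_alphabet must be single-letter codes")
    return model


def _random_orf(rng: np.random.Generator, length: int) -> np.ndarray:
    arr = rng.integers(0, 4, size=length).astype(np.uint8)
    arr[:3] = (0, 3, 2)    # ATG
    arr[-3:] = (3, 0, 0)   # TAA
    return arr


def _mutate(arr: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    if divergence <= 0:
        return arr.copy()
    out = arr.copy()
    mask = rng.random(arr.size) < divergence
    n = int(mask.sum())
    if n:
        # substitute with one of the three other bases, uniformly
        out[mask] = (out[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return out


@lru_cache(maxsize=8)
def ancestral_families(model: SpeciesModel) -> tuple[GeneFamilyAncestor, ...]:
    """Deterministic family inventory (ancestors) of a species model."""
    rng = np.random.default_rng(model.rng_seed)
    glo, ghi = model.gene_length_range
    lengths = rng.integers(glo // 3, ghi // 3 + 1,
                           size=model.n_core_families + model.n_accessory_families) * 3
    plo, phi = model.accessory_prevalence_range
    fams = []
    for i in range(model.n_core_families):
        fams.append(GeneFamilyAncestor(
            family_id=f"{model.species_id}_F{i:05d}",
            ancestral_sequence=decode_seq(_random_orf(rng, int(lengths[i]))),
            category=str(rng.choice(list(model.category_alphabet))),
            prevalence=1.0,
            strand="+" if rng.random() < 0.5 else "-",
        ))
    for j in range(model.n_accessory_families):
        i = model.n_core_families + j
        fams.append(GeneFamilyAncestor(
            family_id=f"{model.species_id}_A{j:05d}",
            ancestral_sequence=decode_seq(_random_orf(rng, int(lengths[i]))),
            category=str(rng.choice(list(model.category_alphabet))),
            prevalence=float(rng.uniform(plo, phi)),
            strand="+" if rng.random() < 0.5 else "-",
        ))
    return tuple(fams)


def round_half_even(x: float) -> int:
    return int(np.rint(x))


def _layout_order(model: SpeciesModel, n_families: int) -> np.ndarray:
    # fixed gene order shared by all genomes (no rearrangement simulation)
    rng = np.random.default_rng(model.rng_seed + 1)
    return rng.permutation(n_families)


def sample_genomes(model: SpeciesModel, n: int, seed: int,
                   genus_partner: bool = False,
                   id_prefix: str | None = None) -> list[Genome]:
    """Sample ``n`` complete genomes of the species.

    Every genome carries exactly one copy of each core family; accessory
    family ``f`` is present in ``round(prevalence_f * n)`` genomes
    (round-half-to-even); each genome additionally carries its own unique
    genes.  Gene order is identical across genomes; intergenic spacer
    lengths and sequences are drawn independently per genome.

    With ``genus_partner=True`` the genomes come from the sister species of
    the same genus: every ancestor is first re-mutated at
    ``model.genus_divergence`` (deterministically from the model seed), the
    family ids get a ``@genus`` suffix, and sampling proceeds as usual.
    """
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    fams = ancestral_families(model)
    prefix = id_prefix or (f"{model.species_id}_gp" if genus_partner else model.species_id)
    if genus_partner:
        grng = np.random.default_rng(model.rng_seed + 2)
        fams = tuple(
            replace(f,
                    family_id=f.family_id + "@genus",
                    ancestral_sequence=decode_seq(
                        _mutate(encode_seq(f.ancestral_sequence), model.genus_divergence, grng)))
            for f in fams)

    order = _layout_order(model, len(fams))
    rng = np.random.default_rng(seed)

    # which genomes carry each accessory family (round-half-to-even rule)
    presence = np.ones((len(fams), n), dtype=bool)
    for fi, fam in enumerate(fams):
        if fam.prevalence < 1.0:
            k = round_half_even(fam.prevalence * n)
            carriers = rng.choice(n, size=k, replace=False)
            presence[fi] = False
            presence[fi, carriers] = True

    ancestors = [encode_seq(f.ancestral_sequence) for f in fams]
    ilo, ihi = model.intergenic_length_range
    glo, ghi = model.gene_length_range
    genomes = []
    for g in range(n):
        genome_id = f"{prefix}_G{g:03d}"
        parts: list[np.ndarray] = []
        annotations: list[GeneAnnotation] = []
        pos = 0
        gene_idx = 0

        def _place(seq_arr: np.ndarray, family_id: str, strand: str, category: str):
            nonlocal pos, gene_idx
            spacer = rng.integers(ilo, ihi + 1)
            parts.append(rng.integers(0, 4, size=spacer).astype(np.uint8))
            pos += int(spacer)
            embedded = (3 - seq_arr[::-1]) if strand == "-" else seq_arr
            parts.append(embedded)
            annotations.append(GeneAnnotation(
                gene_id=f"{genome_id}_g{gene_idx:05d}", family_id=family_id,
                start=pos, end=pos + seq_arr.size, strand=strand, category=category))
            pos += seq_arr.size
            gene_idx += 1

        for fi in order:
            if not presence[fi, g]:
                continue
            fam = fams[fi]
            member = _mutate(ancestors[fi], model.within_family_divergence, rng)
            _place(member, fam.family_id, fam.strand, fam.category)
        for u in range(model.unique_genes_per_genome):
            length = int(rng.integers(glo // 3, ghi // 3 + 1)) * 3
            _place(_random_orf(rng, length), f"{genome_id}_U{u:03d}",
                   "+" if rng.random() < 0.5 else "-",
                   str(rng.choice(list(model.category_alphabet))))
        # closing spacer keeps the chromosome circular without origin-spanning genes
        parts.append(rng.integers(0, 4, size=int(rng.integers(ilo, ihi + 1))).astype(np.uint8))
        sequence = decode_seq(np.concatenate(parts))
        genome = Genome(genome_id=genome_id, sequence=sequence, annotations=annotations)
        assert sum(a.length for a in annotations) < genome.length
        genomes.append(genome)
    return genomes


# ---------------------------------------------------------------------------
# dataset I/O: FASTA + GFF3 + manifest
# ---------------------------------------------------------------------------

_GFF_COLS = 9


def write_dataset(genomes: list[Genome], directory, seed: int | None = None) -> list[Path]:
    """Write one FASTA + one GFF3 per genome plus a ``manifest.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest_lines = ["genome_id\tfasta\tgff\tseed"]
    for genome in genomes:
        fasta = directory / f"{genome.genome_id}.fna"
        gff = directory / f"{genome.genome_id}.gff"
        SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.genome_id, description="")],
                    str(fasta), "fasta")
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {genome.genome_id} 1 {genome.length}\n")
            for ann in genome.annotations:
                attrs = (f"ID={ann.gene_id};locus_tag={ann.gene_id};"
                         f"family_id={ann.family_id};cog_category={ann.category}")
                fh.write("\t".join([genome.genome_id, "panmag", "CDS",
                                    str(ann.start + 1), str(ann.end), ".",
                                    ann.strand, "0", attrs]) + "\n")
        manifest_lines.append(
            f"{genome.genome_id}\t{fasta.name}\t{gff.name}\t{'' if seed is None else seed}")
        paths.extend([fasta, gff])
    (directory / "manifest.tsv").write_text("\n".join(manifest_lines) + "\n")
    return paths


def _parse_gff(path: Path, genome_id: str, genome_length: int) -> list[GeneAnnotation]:
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise ParseError(f"expected {_GFF_COLS} columns, got {len(cols)}",
                                 path, lineno)
            try:
                start = int(cols[3]) - 1
                end = int(cols[4])
            except ValueError:
                raise ParseError("non-integer coordinates", path, lineno) from None
            if not (0 <= start < end):
                raise ParseError(f"invalid interval {start + 1}..{end}", path, lineno)
            if end > genome_length:
                raise ParseError(f"end {end} exceeds sequence length {genome_length}",
                                 path, lineno)
            if cols[6] not in "+-":
                raise ParseError(f"invalid strand {cols[6]!r}", path, lineno)
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            if "ID" not in attrs:
                raise ParseError("missing ID attribute", path, lineno)
            annotations.append(GeneAnnotation(
                gene_id=attrs["ID"], family_id=attrs.get("family_id", attrs["ID"]),
                start=start, end=end, strand=cols[6],
                category=attrs.get("cog_category", "S")))
    return annotations


def read_dataset(directory) -> list[Genome]:
    """Read a dataset written by :func:`write_dataset` (round-trip identity)."""
    directory = Path(directory)
    manifest = directory / "manifest.tsv"
    if manifest.exists():
        rows = manifest.read_text().strip().split("\n")[1:]
        pairs = [(directory / r.split("\t")[1], directory / r.split("\t")[2]) for r in rows]
    else:
        pairs = [(f, f.with_suffix(".gff")) for f in sorted(directory.glob("*.fna"))]
    if not pairs:
        warnings.warn(f"no genomes found in {directory}", stacklevel=2)
        return []
    genomes = []
    for fasta, gff in pairs:
        try:
            records = list(SeqIO.parse(str(fasta), "fasta"))
        except Exception as exc:  # malformed FASTA
            raise ParseError(f"unreadable FASTA: {exc}", fasta) from exc
        if len(records) != 1:
            raise ParseError(f"expected a single record, found {len(records)}", fasta)
        rec = records[0]
        if not gff.exists():
            raise ParseError("missing GFF3 companion file", gff)
        annotations = _parse_gff(gff, rec.id, len(rec.seq))
        genomes.append(Genome(genome_id=rec.id, sequence=str(rec.seq),
                              annotations=annotations))
    return genomes
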