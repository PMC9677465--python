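"""Coordinate-driven gene recovery from contigs.

Real pipelines differ in how their gene finder treats genes running off a
contig edge: normal-mode prediction (Prodigal inside Prokka, as used by
Roary- and BPGA-style workflows) effectively loses them, while metagenome
mode (the Anvi'o default) emits the retained fragment as a partial call.
Because every contig carries provenance to an annotated source genome, gene
calling here is a deterministic lift of the ground-truth annotations onto
the contigs, with the two edge-behaviours made explicit:

* a gene fully contained in a contig yields a full-length call in both modes;
* a gene truncated by a contig edge yields nothing in ``normal`` mode, and in
  ``meta`` mode the retained piece (trimmed to codon phase) if it is at least
  ``max(min_partial_fraction * gene length, min_call_length)`` long;
* contaminant contigs are lifted against their own source's annotations, with
  ``from_contaminant=True``;
* optionally, each truncation event emits a junk call with probability
  ``spurious_rate`` (family sentinel ``"SPURIOUS"``), modelling frame-shifted
  false predictions.  The default of 0 keeps the mechanism deterministic.

Codon trimming snaps the 5' offset of a retained piece up to the next codon
boundary of the annotated reading frame and the piece length down to a
multiple of 3, so 5'-intact pieces keep the annotated start frame and
3'-intact pieces keep the annotated end frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigurationError
from .magsim import MAG, Contig
from .species import Genome, decode_seq

SPURIOUS_FAMILY = "SPURIOUS"


@dataclass(frozen=True)
class CallingParams:
    mode: str = "normal"  # normal | meta
    min_partial_fraction: float = 0.5
    min_call_length: int = 90
    spurious_rate: float = 0.0

    def __post_init__(self):
        if self.mode not in ("normal", "meta"):
            raise ConfigurationError(f"bad calling mode {self.mode!r}")
        if not (0.0 < self.min_partial_fraction <= 1.0):
            raise ConfigurationError("min_partial_fraction must be in (0,1]")
        if self.min_call_length < 0:
            raise ConfigurationError("min_call_length must be >= 0")
        if not (0.0 <= self.spurious_rate <= 1.0):
            raise ConfigurationError("spurious_rate must be in [0,1]")


@dataclass
class GeneCall:
    call_id: str
    assembly_id: str
    family_id: str  # ground-truth oracle; never fed to clustering
    sequence: str
    partial_5prime: bool = False
    partial_3prime: bool = False
    from_contaminant: bool = False
    gene_offset: int = 0  # 5' offset of the call within its source gene
    source_gene_id: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


def assembly_id_of(assembly: Genome | MAG) -> str:
    return assembly.genome_id if isinstance(assembly, Genome) else assembly.mag_id


def _full_calls(genome: Genome, assembly_id: str) -> list[GeneCall]:
    return [GeneCall(call_id=ann.gene_id, assembly_id=assembly_id,
                     family_id=ann.family_id, sequence=genome.gene_sequence(ann),
                     source_gene_id=ann.gene_id)
            for ann in genome.annotations]


def _lift_contig(contig: Contig, source: Genome, params: CallingParams,
                 assembly_id: str, counter, rng) -> list[GeneCall]:
    calls: list[GeneCall] = []
    g = source.length
    s, e = contig.source_interval
    for ann in source.annotations:
        # consider the annotation in both windings of the circular coordinate
        for shift in (0, g):
            a0, a1 = ann.start + shift, ann.end + shift
            ov0, ov1 = max(s, a0), min(e, a1)
            if ov1 - ov0 <= 0:
                continue
            length = ann.length
            retained = ov1 - ov0
            if retained == length:
                calls.append(GeneCall(
                    call_id=f"{assembly_id}_c{next(counter):05d}",
                    assembly_id=assembly_id, family_id=ann.family_id,
                    sequence=source.gene_sequence(ann),
                    from_contaminant=contig.is_contaminant,
                    source_gene_id=ann.gene_id))
                continue
            # truncation event: the contig edge cuts through this gene
            if params.spurious_rate > 0 and rng.random() < params.spurious_rate:
                junk_len = int(rng.integers(30, 101)) * 3
                calls.append(GeneCall(
                    call_id=f"{assembly_id}_c{next(counter):05d}",
                    assembly_id=assembly_id, family_id=SPURIOUS_FAMILY,
                    sequence=decode_seq(rng.integers(0, 4, junk_len).astype(np.uint8)),
                    from_contaminant=contig.is_contaminant,
                    source_gene_id=""))
            if params.mode == "normal":
                continue
            # gene-oriented 5' offset of the retained piece
            if ann.strand == "+":
                off5 = ov0 - a0
            else:
                off5 = a1 - ov1
            # snap to the annotated reading frame
            new_off5 = -(-off5 // 3) * 3
            plen = (retained - (new_off5 - off5)) // 3 * 3
            if retained < max(params.min_partial_fraction * length,
                              params.min_call_length) or plen < 3:
                continue
            member = source.gene_sequence(ann)
            piece = member[new_off5:new_off5 + plen]
            calls.append(GeneCall(
                call_id=f"{assembly_id}_c{next(counter):05d}",
                assembly_id=assembly_id, family_id=ann.family_id,
                sequence=piece,
                partial_5prime=new_off5 > 0,
                partial_3prime=new_off5 + plen < length,
                from_contaminant=contig.is_contaminant,
                gene_offset=new_off5, source_gene_id=ann.gene_id))
    return calls


def call_genes(assembly: Genome | MAG, params: CallingParams,
               genomes: dict[str, Genome] | None = None,
               seed: int = 0) -> list[GeneCall]:
    """Recover gene calls from an assembly.

    ``genomes`` maps genome ids to annotated source genomes and is required
    for MAGs (parent and any contamination donors must be present).  For a
    complete :class:`Genome` the calls are exactly its annotations in either
    mode.
    """
    if isinstance(assembly, Genome):
        return _full_calls(assembly, assembly.genome_id)
    rng = np.random.default_rng(seed)
    counter = iter(range(10 ** 9))
    calls: list[GeneCall] = []
    for contig in sorted(assembly.contigs, key=lambda c: c.contig_id):
        source = (genomes or {}).get(contig.source_genome_id)
        if source is None:
            raise ConfigurationError(
                f"contig {contig.contig_id} has no provenance genome "
                f"{contig.source_genome_id!r}")
        calls.extend(_lift_contig(contig, source, params, assembly.mag_id,
                                  counter, rng))
    return calls


def call_dataset(assemblies: list[Genome | MAG], params: CallingParams,
                 genomes: dict[str, Genome] | None = None,
                 seed: int = 0) -> list[GeneCall]:
    """Call genes on every assembly of a dataset with per-assembly seeds."""
    rng = np.random.default_rng(seed)
    out: list[GeneCall] = []
    for assembly in assemblies:
        out.extend(call_genes(assembly, params, genomes,
                              seed=int(rng.integers(2 ** 31))))
    return out


def write_calls(calls: list[GeneCall], directory, prefix: str = "calls") -> None:
    """Nucleotide + translated FASTA and a separate oracle TSV.

    The FASTA headers carry only what a real pipeline would know (assembly,
    partial flags); family ids and contaminant status go to the oracle TSV,
    which is never fed to clustering.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / f"{prefix}.ffn", "w") as nt, \
            open(directory / f"{prefix}.faa", "w") as aa:
        for c in calls:
            header = (f">{c.call_id} assembly={c.assembly_id} "
                      f"partial={int(c.partial_5prime)}{int(c.partial_3prime)}")
            nt.write(f"{header}\n{c.sequence}\n")
            aa.write(f"{header}\n{Seq(c.sequence).translate()}\n")
    pd.DataFrame([dict(call_id=c.call_id, assembly_id=c.assembly_id,
                       family_id=c.family_id, from_contaminant=int(c.from_contaminant),
                       gene_offset=c.gene_offset, source_gene_id=c.source_gene_id)
                  for c in calls]).to_csv(directory / f"{prefix}.oracle.tsv",
                                          sep="\t", index=False)
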