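"""Degrade complete genomes into simulated MAGs.

The three-step workflow mirrors how binning artefacts show up in real
metagenome-assembled genomes:

1. *fragmentation* — cut the circular chromosome at ``k`` uniform positions,
   producing exactly ``k`` contigs whose lengths sum to the genome length;
2. *incompleteness* — discard whole contigs in random order (trimming only
   the last one) until the requested fraction of the parent's bp is gone;
3. *contamination* — append fragments of a foreign donor genome (same
   species, or the genus-partner species) until the requested fraction of
   the parent's bp has been added.

Realized percentages are exact to within 1 bp of the target; contamination
is expressed relative to the parent genome size before any removal, which
keeps the denominator fixed and auditable.  Contigs keep the orientation of
their source (no reverse-complementing), and every contig records the exact
source interval it was sliced from, so provenance can always be re-checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .species import Genome, round_half_even

#: fragment-count, incompleteness (%) and contamination (%) level grids used
#: throughout the analyses
FRAGMENTATION_GRID = (50, 100, 200, 300, 400)
INCOMPLETENESS_GRID = (1.0, 2.0, 3.0, 4.0, 5.0)
CONTAMINATION_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass
class Contig:
    """A genome slice.  ``source_interval`` is 0-based half-open on the source;
    the end may exceed the source length by up to one wrap of the circular
    chromosome (``end - start <= source length``)."""

    contig_id: str
    sequence: str
    source_genome_id: str
    source_interval: tuple[int, int]
    is_contaminant: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MAG:
    mag_id: str
    parent_genome_id: str
    contigs: list[Contig]
    parent_length: int
    realized_fragments: int
    realized_incompleteness: float = 0.0
    realized_contamination: float = 0.0

    @property
    def length(self) -> int:
        return sum(c.length for c in self.contigs)


@dataclass(frozen=True)
class DegradationProfile:
    """One grid cell of the degradation experiment."""

    fragmentation_mode: str = "fragment_count"  # or "mean_fragment_length"
    fragmentation_level: int = 100
    incompleteness_mean: float = 0.0  # fraction of parent bp removed
    contamination_mean: float = 0.0  # fraction of parent bp added
    contamination_scope: str = "intra_species"  # intra_species | inter_species | none
    sampling: str = "fixed"  # fixed | distribution
    # truncated-normal SDs for sampling="distribution"
    fragmentation_sd: float = 0.0
    incompleteness_sd: float = 0.0
    contamination_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.fragmentation_mode not in ("fragment_count", "mean_fragment_length"):
            raise ConfigurationError(f"bad fragmentation_mode {self.fragmentation_mode!r}")
        if self.fragmentation_level < 1:
            raise ConfigurationError("fragmentation_level must be positive")
        if not (0.0 <= self.incompleteness_mean < 1.0):
            raise ConfigurationError("incompleteness_mean must be in [0,1)")
        if self.contamination_mean < 0.0:
            raise ConfigurationError("contamination_mean must be >= 0")
        if self.contamination_scope not in ("intra_species", "inter_species", "none"):
            raise ConfigurationError(f"bad contamination_scope {self.contamination_scope!r}")
        if self.sampling not in ("fixed", "distribution"):
            raise ConfigurationError(f"bad sampling {self.sampling!r}")

    @property
    def label(self) -> str:
        """Group label, e.g. ``'100cut + 99comp + 2.0cont'``."""
        parts = [f"{self.fragmentation_level}cut"]
        if self.incompleteness_mean > 0:
            parts.append(f"{100 - self.incompleteness_mean * 100:g}comp")
        if self.contamination_mean > 0 and self.contamination_scope != "none":
            parts.append(f"{self.contamination_mean * 100:.1f}cont")
        return " + ".join(parts)


def _slice_circular(seq: str, start: int, end: int) -> str:
    g = len(seq)
    if end <= g:
        return seq[start:end]
    return seq[start:] + seq[:end - g]


def fragment_genome(genome: Genome, mode: str = "fragment_count",
                    level: int | float = 100, seed: int = 0,
                    positions=None) -> MAG:
    """Cut a circular genome into contigs.

    ``fragment_count``: exactly ``level`` cut positions drawn uniformly
    without replacement give exactly ``level`` contigs summing to the genome
    length.  ``mean_fragment_length``: the cut count is
    ``round(length / level)``.  Explicit ``positions`` (sorted, distinct)
    override the random draw — used for controlled equal-length layouts.
    """
    g = genome.length
    if positions is not None:
        cuts = np.asarray(sorted(set(int(p) for p in positions)))
        if cuts.size < 1 or cuts[0] < 0 or cuts[-1] >= g:
            raise ConfigurationError("cut positions out of range")
    else:
        if mode == "fragment_count":
            k = int(level)
        elif mode == "mean_fragment_length":
            if level > g:
                raise ConfigurationError("mean fragment length exceeds genome length")
            k = max(1, round_half_even(g / level))
        else:
            raise ConfigurationError(f"bad fragmentation mode {mode!r}")
        if k < 1 or k > g:
            raise ConfigurationError(f"fragment count {k} out of range for genome of {g} bp")
        rng = np.random.default_rng(seed)
        cuts = np.sort(rng.choice(g, size=k, replace=False))
    k = cuts.size
    contigs = []
    for i in range(k):
        start = int(cuts[i])
        end = int(cuts[(i + 1) % k]) + (g if i == k - 1 else 0)
        if k == 1:
            end = start + g
        contigs.append(Contig(
            contig_id=f"{genome.genome_id}_ctg{i:04d}",
            sequence=_slice_circular(genome.sequence, start, end),
            source_genome_id=genome.genome_id,
            source_interval=(start, end)))
    assert sum(c.length for c in contigs) == g
    return MAG(mag_id=f"{genome.genome_id}_mag", parent_genome_id=genome.genome_id,
               contigs=contigs, parent_length=g, realized_fragments=k)


def _trim_contig(contig: Contig, keep: int, from_start: bool) -> Contig:
    """Keep ``keep`` bp of a contig, dropping the rest from one end."""
    s, e = contig.source_interval
    if from_start:  # keep the head
        return replace(contig, sequence=contig.sequence[:keep],
                       source_interval=(s, s + keep))
    return replace(contig, sequence=contig.sequence[contig.length - keep:],
                   source_interval=(e - keep, e))


def apply_incompleteness(mag: MAG, target: float, seed: int = 0) -> MAG:
    """Remove whole contigs (trimming only the last) until ``target`` of the
    parent's bp is gone; realized incompleteness is exact to within 1 bp."""
    if not (0.0 <= target < 1.0):
        raise ConfigurationError("incompleteness target must be in [0,1)")
    if target == 0.0:
        return mag
    if len(mag.contigs) < 2:
        raise ConfigurationError("incompleteness requires >= 2 contigs")
    if any(c.is_contaminant for c in mag.contigs):
        raise ConfigurationError("incompleteness must be applied before contamination")
    target_bp = round_half_even(target * mag.parent_length)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(mag.contigs))
    removed_bp = 0
    removed_idx: list[int] = []
    for idx in order:
        removed_bp += mag.contigs[idx].length
        removed_idx.append(int(idx))
        if removed_bp >= target_bp:
            break
    excess = removed_bp - target_bp
    kept = [c for i, c in enumerate(mag.contigs) if i not in set(removed_idx)]
    if excess > 0:
        # hand back `excess` bp of the last-removed contig, from a random end
        last = mag.contigs[removed_idx[-1]]
        kept.append(_trim_contig(last, excess, from_start=bool(rng.integers(2))))
    if not kept:
        raise ConfigurationError("incompleteness target leaves zero contigs")
    kept.sort(key=lambda c: c.contig_id)
    return replace(mag, contigs=kept,
                   realized_incompleteness=target_bp / mag.parent_length)


def add_contamination(mag: MAG, donor_pool: list[Genome], target: float,
                      scope: str = "intra_species",
                      frag_params: tuple[str, int | float] = ("fragment_count", 100),
                      seed: int = 0) -> MAG:
    """Append fragments of a random donor genome until ``target`` of the
    parent's bp has been added (exact to within 1 bp)."""
    if target < 0:
        raise ConfigurationError("contamination target must be >= 0")
    if target == 0.0 or scope == "none":
        return mag
    pool = [g for g in donor_pool if g.genome_id != mag.parent_genome_id]
    if not pool:
        raise ConfigurationError("empty contamination donor pool")
    rng = np.random.default_rng(seed)
    donor = pool[int(rng.integers(len(pool)))]
    donor_mag = fragment_genome(donor, frag_params[0], frag_params[1],
                                seed=int(rng.integers(2 ** 31)))
    target_bp = round_half_even(target * mag.parent_length)
    order = rng.permutation(len(donor_mag.contigs))
    added: list[Contig] = []
    added_bp = 0
    for idx in order:
        c = donor_mag.contigs[idx]
        added.append(c)
        added_bp += c.length
        if added_bp >= target_bp:
            break
    if added_bp < target_bp:
        raise ConfigurationError("donor genome too small for contamination target")
    excess = added_bp - target_bp
    if excess > 0:
        # trim the tail of the last fragment: under a fixed seed the realized
        # contaminant sequence is then nested across increasing target levels
        added[-1] = _trim_contig(added[-1], added[-1].length - excess, from_start=True)
    contigs = list(mag.contigs)
    for i, c in enumerate(added):
        contigs.append(replace(c, contig_id=f"{mag.mag_id}_cont{i:04d}",
                               is_contaminant=True))
    return replace(mag, contigs=contigs,
                   realized_contamination=target_bp / mag.parent_length)


def _draw_levels(profile: DegradationProfile, n: int, rng: np.random.Generator):
    """Per-genome (fragmentation, incompleteness, contamination) levels."""
    if profile.sampling == "fixed":
        return ([profile.fragmentation_level] * n,
                [profile.incompleteness_mean] * n,
                [profile.contamination_mean] * n)

    def trunc_normal(mean, sd, lo, hi, size, integer=False):
        if sd <= 0:
            vals = np.full(size, mean, dtype=float)
        else:
            vals = rng.normal(mean, sd, size=size)
            vals = np.clip(vals, lo, hi)
        return np.rint(vals).astype(int) if integer else vals

    frags = trunc_normal(profile.fragmentation_level, profile.fragmentation_sd,
                         1, np.inf, n, integer=True)
    incs = trunc_normal(profile.incompleteness_mean, profile.incompleteness_sd,
                        0.0, 0.999, n)
    conts = trunc_normal(profile.contamination_mean, profile.contamination_sd,
                         0.0, np.inf, n)
    return list(frags), list(incs), list(conts)


def simulate_dataset(genomes: list[Genome], profile: DegradationProfile,
                     donors: list[Genome] | None = None,
                     seed: int = 0) -> tuple[list[MAG], pd.DataFrame]:
    """Apply fragmentation -> incompleteness -> contamination to every genome.

    Returns the MAGs and a manifest of realized statistics.  Step seeds are
    derived deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    frags, incs, conts = _draw_levels(profile, len(genomes), rng)
    step_seeds = rng.integers(2 ** 31, size=(len(genomes), 3))
    mags, rows = [], []
    for i, genome in enumerate(genomes):
        mag = fragment_genome(genome, profile.fragmentation_mode, frags[i],
                              seed=int(step_seeds[i, 0]))
        if incs[i] > 0:
            mag = apply_incompleteness(mag, float(incs[i]), seed=int(step_seeds[i, 1]))
        if conts[i] > 0 and profile.contamination_scope != "none":
            mag = add_contamination(
                mag, donors or [], float(conts[i]), scope=profile.contamination_scope,
                frag_params=(profile.fragmentation_mode, profile.fragmentation_level),
                seed=int(step_seeds[i, 2]))
        mags.append(mag)
        rows.append(dict(mag_id=mag.mag_id, parent_genome_id=mag.parent_genome_id,
                         fragments=mag.realized_fragments,
                         incompleteness=mag.realized_incompleteness,
                         contamination=mag.realized_contamination,
                         n_contigs=len(mag.contigs), total_bp=mag.length))
    return mags, pd.DataFrame(rows)


def make_mixed_dataset(genomes: list[Genome], mags: list[MAG],
                       mag_fraction: float, seed: int = 0) -> list[Genome | MAG]:
    """Replace ``round(mag_fraction% * n)`` genomes by their paired MAGs.

    A parent contributes either its complete genome or its MAG, never both.
    """
    if not (0.0 <= mag_fraction <= 100.0):
        raise ConfigurationError("mag_fraction must be in [0,100]")
    by_parent = {m.parent_genome_id: m for m in mags}
    genome_ids = {g.genome_id for g in genomes}
    unpaired = set(by_parent) - genome_ids
    if unpaired:
        raise ConfigurationError(f"MAG(s) without a paired genome: {sorted(unpaired)}")
    k = round_half_even(mag_fraction * len(genomes) / 100.0)
    eligible = sorted(p for p in by_parent)
    if k > len(eligible):
        raise ConfigurationError(f"need {k} MAGs but only {len(eligible)} are paired")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(eligible, size=k, replace=False)) if k else set()
    return [by_parent[g.genome_id] if g.genome_id in chosen else g for g in genomes]


def write_mag(mag: MAG, directory) -> None:
    """Multi-record FASTA plus a provenance TSV for one MAG."""
    from pathlib import Path

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    SeqIO.write([SeqRecord(Seq(c.sequence), id=c.contig_id, description="")
                 for c in mag.contigs], str(directory / f"{mag.mag_id}.fna"), "fasta")
    rows = [dict(contig_id=c.contig_id, source_genome_id=c.source_genome_id,
                 start=c.source_interval[0], end=c.source_interval[1],
                 is_contaminant=int(c.is_contaminant)) for c in mag.contigs]
    pd.DataFrame(rows).to_csv(directory / f"{mag.mag_id}.provenance.tsv",
                              sep="\t", index=False)
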