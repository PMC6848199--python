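"""Assign an evolutionary age to a query sequence from homolog hits.

This is the rule used for sequences that lack a precomputed family-based
age (e.g. non-coding sequences): search the sequence against a panel of
completely sequenced genomes, keep significant hits, and report the most
recent common ancestor of human and the most distant genome with a hit.
On a linear human-lineage timeline that is simply the oldest taxon among
the branch-off points of the hit genomes; a sequence with no hits
outside human is assigned to the youngest (human-only) bucket.

The reported divergence time is a lower bound: the sequence could have
arisen anywhere along the branch to which it is assigned.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import LookupError_, ValidationError
from .timeline import Timeline

__all__ = ["HitProfile", "parse_blast_tab", "mrca_age", "load_genome_map"]

_BLAST6_NCOLS = 12  # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore


@dataclass(frozen=True)
class HitProfile:
    """Set of genome labels with a significant hit for one query."""

    query_id: str
    hit_genomes: frozenset[str]


def parse_blast_tab(
    path: str | Path,
    max_evalue: float = 1e-3,
    subject_genome: Mapping[str, str] | None = None,
) -> tuple[list[HitProfile], list[str]]:
    """Parse BLAST tabular output (outfmt 6) into per-query hit profiles.

    Parameters
    ----------
    path
        12-column tab-separated BLAST output.
    max_evalue
        Hits with E-value strictly greater than this are discarded.
        The significance threshold is a package choice (no universal
        cutoff exists); 1e-3 by default.
    subject_genome
        Optional map from subject sequence id to genome label.  When
        omitted the subject id itself is used as the genome label.
        Subjects missing from the map are collected into the returned
        reject list rather than failing the parse.

    Returns
    -------
    (profiles, rejected)
        One :class:`HitProfile` per query id (in first-appearance
        order), and the list of unmappable subject ids encountered.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"BLAST file not found: {path}")
    genomes: dict[str, set[str]] = {}
    rejected: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _BLAST6_NCOLS:
                raise ValidationError(
                    f"{path}:{lineno}: expected {_BLAST6_NCOLS} tab-separated "
                    f"columns, got {len(cols)}"
                )
            qseqid, sseqid = cols[0], cols[1]
            try:
                evalue = float(cols[10])
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: E-value {cols[10]!r} is not a number"
                ) from None
            genomes.setdefault(qseqid, set())
            if evalue > max_evalue:
                continue
            if subject_genome is None:
                genome = sseqid
            elif sseqid in subject_genome:
                genome = subject_genome[sseqid]
            else:
                rejected.append(sseqid)
                continue
            genomes[qseqid].add(genome)
    profiles = [
        HitProfile(query_id=q, hit_genomes=frozenset(g)) for q, g in genomes.items()
    ]
    return profiles, rejected


def mrca_age(
    profile: HitProfile,
    genome_to_taxon: Mapping[str, str],
    timeline: Timeline,
) -> int:
    """Taxon index of the MRCA of human and the most distant hit genome.

    ``genome_to_taxon`` maps each genome label to the timeline taxon at
    which its lineage branches off the human lineage.  The result is the
    OLDEST (smallest) taxon index among the mapped hit genomes; an empty
    profile maps to the youngest taxon (a human-restricted sequence).
    Monotone in the hit set: adding genomes can only make the age older.
    """
    if not profile.hit_genomes:
        return timeline.k
    indices = []
    for genome in profile.hit_genomes:
        try:
            taxon = genome_to_taxon[genome]
        except KeyError:
            raise LookupError_(
                f"genome {genome!r} missing from genome->taxon map"
            ) from None
        indices.append(timeline.index_of(taxon))
    return min(indices)


def load_genome_map(path: str | Path) -> dict[str, str]:
    """Read a ``genome,taxon`` CSV into a genome -> taxon dict."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"genome map not found: {path}")
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if lineno == 1 and [c.strip().lower() for c in row[:2]] == ["genome", "taxon"]:
                continue
            if len(row) < 2:
                raise ValidationError(f"{path}:{lineno}: expected 'genome,taxon'")
            out[row[0].strip()] = row[1].strip()
    return out
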