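"""Assign ages to sequences from homolog-hit profiles (BLAST tabular).

For sequences without a family-based age (e.g. non-coding sequences),
age is assigned by the most-recent-common-ancestor rule: the oldest
timeline taxon among the branch-off points of genomes with a
significant hit.  The reported divergence time is a lower bound on the
sequence's origin.
"""

import tempfile
from pathlib import Path

from geneage import default_timeline, mrca_age, parse_blast_tab

timeline = default_timeline()
genome_to_taxon = {
    "S_cerevisiae": "Opisthokonta",
    "D_melanogaster": "Bilateria",
    "D_rerio": "Euteleostomi",
    "M_musculus": "Euarchontoglires",
    "P_troglodytes": "Homininae",
}

rows = [
    ("ncRNA_1", "S_cerevisiae", "1e-40"),   # deep homology -> very old
    ("ncRNA_1", "M_musculus", "1e-80"),
    ("ncRNA_2", "P_troglodytes", "1e-20"),  # primate-only -> young
    ("ncRNA_3", "D_rerio", "0.8"),          # insignificant -> human-restricted
]
blast = "\n".join(
    f"{q}\t{s}\t97.0\t100\t3\t0\t1\t100\t1\t100\t{e}\t180.0" for q, s, e in rows
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "hits.tsv"
    path.write_text(blast + "\n")
    profiles, rejected = parse_blast_tab(path, max_evalue=1e-3)

print(f"{'query':<10}{'hit genomes':<32}{'assigned taxon':<20}age (Ma)")
for profile in profiles:
    idx = mrca_age(profile, genome_to_taxon, timeline)
    taxon = timeline.taxon_at(idx)
    hits = ", ".join(sorted(profile.hit_genomes)) or "(none)"
    print(f"{profile.query_id:<10}{hits:<32}{taxon:<20}{timeline.ages[idx - 1]:.0f}")
print("\nThe oldest hit genome sets the age (monotone in the hit set); an")
print("empty profile falls in the youngest, human-restricted bucket.")
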