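"""Simulate a study and summarize each class's age distribution.

Generates the built-in ten-class synthetic study (realistic class sizes,
three planted profile families over the 16-taxon human lineage), builds
each class's cumulative origination curve and prints its median
evolutionary age in Ma — the time point by which half the class's genes
had originated.  Older classes have larger medians.
"""

from geneage import build_distribution, default_timeline, join_ages, median_age
from geneage.synthetic import paper_like_spec, simulate_study

timeline = default_timeline()
age_table, catalog = simulate_study(paper_like_spec(), timeline, seed=1)
joined = join_ages(catalog, age_table)

print(f"universe: {len(age_table)} genes, {len(catalog)} classes\n")
print(f"{'class':<18}{'n':>6}  median age (Ma)")
rows = []
for name, ages in joined.ages.items():
    dist = build_distribution(name, ages, timeline)
    rows.append((median_age(dist, timeline), name, dist.n))
for med, name, n in sorted(rows, reverse=True):
    print(f"{name:<18}{n:>6}  {med:8.1f}")
print("\nLarger medians = evolutionarily older classes; the three planted")
print("profile families separate into old (~850 Ma), intermediate (~650 Ma)")
print("and young (~200 Ma) groups.")
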