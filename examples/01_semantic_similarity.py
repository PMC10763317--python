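"""Disease semantic similarity on a toy ontology.

Builds a six-term disease DAG, computes each term's decayed ancestor
profile (decay 0.5 per level, max over paths), and prints the pairwise
semantic similarity matrix.  Values near 1 mean two diseases share most
of their (weighted) ancestry; 0 means disjoint ontology branches.
"""

from gcnlda import DiseaseOntology, disease_similarity_matrix, semantic_contributions

ontology = DiseaseOntology([
    ("disease", "cancer"),
    ("disease", "metabolic"),
    ("cancer", "lung-cancer"),
    ("cancer", "breast-cancer"),
    ("metabolic", "diabetes"),
])

profile = semantic_contributions(ontology, "lung-cancer", delta=0.5)
print("semantic profile of lung-cancer:")
for term, value in sorted(profile.contributions.items(), key=lambda kv: -kv[1]):
    print(f"  {term:15s} {value:.3f}")
print(f"semantic value DV = {profile.dv:.3f}\n")

ids = ["lung-cancer", "breast-cancer", "diabetes"]
matrix = disease_similarity_matrix(ontology, ids, delta=0.5)
print("pairwise semantic similarity:")
print("  " + "  ".join(f"{d:>13s}" for d in ids))
for i, d in enumerate(ids):
    row = "  ".join(f"{matrix.values[i, j]:13.3f}" for j in range(len(ids)))
    print(f"  {d:13s} {row}")
print("\nThe two cancers share the 'cancer' and root terms, so their")
print("similarity is high; diabetes shares only the root, so it is low.")
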