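"""Cluster a set of fragments by fingerprint similarity.

Computes linear-path fingerprints for a few carboxylic acids and
aromatics, joins pairs whose Tanimoto coefficient reaches 0.5, and
prints the resulting connected-component clusters with their
representatives (the member most similar on average to the rest).
"""

from molblocks import cluster_fragments, linear_path_fingerprint, tanimoto

FRAGMENTS = [
    "CC(=O)O", "CCC(=O)O", "CCCC(=O)O",       # short fatty acids
    "O=C(O)c1ccccc1", "O=C(O)c1ccccc1Cl",     # benzoic acids
    "c1ccccc1", "OCCO",
]

print("pairwise Tanimoto of the two benzoic acids:",
      round(tanimoto(linear_path_fingerprint("O=C(O)c1ccccc1"),
                     linear_path_fingerprint("O=C(O)c1ccccc1Cl")), 3))

for cluster in cluster_fragments(FRAGMENTS, threshold=0.5):
    members = ", ".join(sorted(cluster.members))
    print(f"cluster {cluster.cluster_id} (rep {cluster.representative}): "
          f"{members}")

# Clusters group chemically related fragments: the aliphatic acids end up
# together, as do the two benzoic acids; unrelated fragments stay
# singletons.  Raising the threshold only splits clusters, never merges.
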