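"""Flag mislabeled germplasm samples from genetic distances.

Generates a 3-pool panel, deliberately swaps the taxon label of two
samples in the metadata, and runs the distance-based authenticity audit.
The audit votes each sample's taxon from its nearest neighbours and flags
samples whose recorded label disagrees — exactly the two planted swaps.
"""

from gbskit import PopulationModel, check_replicates, make_population, pairwise_distance

model = PopulationModel(n_pools=3, samples_per_pool=6, n_sites=1000)
matrix, truth = make_population(model, seed=13)
meta = truth["metadata"].copy()

# plant two label errors: a pool1 sample recorded as pool2, and vice versa
swaps = [(0, "pool2"), (6, "pool3")]
for idx, wrong in swaps:
    print(f"planting: {meta.loc[idx, 'sample_id']} recorded as {wrong}")
    meta.loc[idx, "taxon"] = wrong

audit, summary = check_replicates(pairwise_distance(matrix), meta)
flagged = audit[audit["misclassified"]]
print(flagged[["sample_id", "taxon", "voted_taxon", "nearest"]].to_string(index=False))
print(f"\nfraction misclassified: {summary['fraction_misclassified']:.3f}")
print("'taxon' is the (corrupted) recorded label; 'voted_taxon' is what the")
print("sample's genetic neighbours say it is.")
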