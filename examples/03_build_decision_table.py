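"""From annotation + expression + fragments to a rough-set decision table.

Applies the exon filters (internal in every transcript, >= 50 bp, >= 360 bp
flanking introns, no overlap), drops the top-20% expressed genes, computes
inclusion levels (exon expression over the top-10-exon gene mean), labels
exons 'spliced out' (< 0.4) or 'included' ([0.9, 1.1]), binarizes the marks
and removes exons with no modification present.
"""

import histosplice as hs

rule = hs.PlantedRule(
    conditions=(("M01", "preceding", "present"), ("M02", "exon", "present")),
    target_class="spliced_out", penetrance=1.0,
)
config = hs.SyntheticConfig(n_genes=150, n_marks=4, planted_rules=(rule,),
                            seed=3)
dataset = hs.SyntheticDataset.generate(config)

table, internal, labeled, tracks = hs.build_synthetic_table(dataset)

counts = table.class_counts()
print(f"internal exons passing the positional filters: {len(internal)}")
print(f"labelled exons entering the table: {(labeled['label'] != 'unlabeled').sum()}")
print(f"decision table after dropping unmodified exons: {table.n_objects} exons "
      f"x {len(table.attribute_names)} attributes")
print(f"classes: spliced_out={counts['spliced_out']} "
      f"included={counts['included']}")

truth = dataset.labels.set_index("exon_id")["label"]
agree = (table.decision == truth.loc[table.decision.index]).mean()
print(f"labels agree with generator ground truth on {agree:.0%} of exons "
      "(exact by construction at zero expression noise)")
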