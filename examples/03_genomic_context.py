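"""Place annotated copies in genomic context.

Derives pericentromeric euchromatin (PE) by walking euchromatic bp from the
pericentric-heterochromatin boundary, assigns each copy its compartment,
clusters insertions within 10 kb (single linkage, edge-to-edge), and finds
gene associations within transcription borders or a 1-kb flank.
"""

from ltrscape import (
    CompartmentMap,
    SamplingParams,
    annotate_genome,
    assign_compartment,
    associate_genes,
    build_family_library,
    cluster_insertions,
    default_blueprints,
    derive_pericentromeric_euchromatin,
    index_genome,
    scan,
    synthesize_genome,
)

families = build_family_library(n_families=6, seed=1)
sg = synthesize_genome(
    default_blueprints(arm_length=400_000, n_arms=2),
    families,
    params=SamplingParams(n_insertions=60),
    seed=7,
)
copies = annotate_genome(
    sg.genome, families, scan(families, sg.genome, index=index_genome(sg.genome))
).copies

cmap = CompartmentMap.from_intervals(sg.compartments)
# scaled-down PE walk: 30 kb of euchromatin proximal to the PH per arm
cmap = derive_pericentromeric_euchromatin(cmap, pe_size=30_000)
tally = {}
for c in copies:
    c.compartment = assign_compartment(c, cmap)
    tally[c.compartment] = tally.get(c.compartment, 0) + 1
print("copies per compartment:", dict(sorted(tally.items())))
print("(PH pericentric het, DIH/CIH intercalary het, PE the euchromatin "
      "walked from the PH edge, NPE the rest)")

for arm in sorted(cmap.arms):
    arm_copies = [c for c in copies if c.arm == arm]
    clusters, n_clustered = cluster_insertions(arm_copies, distance=10_000)
    multi = sum(1 for cl in clusters if len(cl) >= 2)
    print(f"{arm}: {n_clustered}/{len(arm_copies)} insertions in {multi} clusters "
          "(members within 10 kb of each other)")

npe = [c for c in copies if c.compartment == "NPE"]
assoc = associate_genes(npe, sg.genes, flank=1000)
print(f"gene associations in the NPE: {len(assoc)} "
      f"({sum(1 for a in assoc if a.proximity == 0)} inside genes, "
      f"rest within 1 kb of one)")
for a in assoc[:3]:
    where = a.region if a.proximity == 0 else f"{a.region} at {a.proximity} bp"
    print(f"  {a.copy_id} ~ {a.gene_id}: {where}")
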