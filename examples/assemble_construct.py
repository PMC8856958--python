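"""Embed guides into scaffolds and assemble an annotated expression construct.

Takes three designed guides, embeds the top one into the single-hairpin
mirE template and four (here: recycled) guides into the four-hairpin
polycistron, then assembles a promoter/ORF/3'-UTR construct with
BsrGI+AscI / SalI flanks and validates restriction-site uniqueness.
"""

import shmirkit as sk
from shmirkit.scaffold import BackboneSpec, UniquenessError, write_genbank

txome, _ = sk.make_transcriptome(sk.TxomeSpec(seed=11))
guides = sk.design_guides(txome.target_isoforms(), txome, n_select=4).guides

insert = sk.embed_mirE(guides[0])
print(f"mirE insert: {len(insert)} nt "
      f"(fixed scaffold {sk.MIRE_TEMPLATE.fixed_length} nt + 44 nt duplex)")
slots = sk.extract_slots(sk.MIRE_TEMPLATE, insert)
print(f"  sense slot recovered verbatim: {slots['sense_1'] == guides[0].sense22}")

poly = sk.embed_polycistron(guides[:4])
print(f"polycistron insert: {len(poly)} nt, "
      f"{sum(poly.count(g.antisense22) for g in guides[:4])} guide strands embedded")

backbone = BackboneSpec(
    promoter_name="hSyn",
    promoter_seq="CAGGGTTTCCTGATT",          # synthetic stand-in promoter fragment
    orf=sk.NucSequence("hM4Di_CFP", "ATG" + "GCT" * 20 + "TAA"),
    utr3_spacer="CATCAT",
    utr3_remainder="AGGCCTAGGCCT",
)
# guides can themselves re-create a flank recognition site; pick the
# highest-ranked guide whose insert passes the uniqueness validation
construct = None
for rank, g in enumerate(guides, 1):
    candidate_insert = sk.embed_mirE(g)
    try:
        construct = sk.assemble_construct(candidate_insert, backbone)
        print(f"\nassembled construct from rank-{rank} guide")
        break
    except UniquenessError as err:
        print(f"\nrank-{rank} guide rejected by site validation: {err}")
print(f"assembled construct: {len(construct.full_sequence)} nt")
for name, ftype, s, e in construct.features:
    print(f"  {name:<14} {ftype:<16} [{s}, {e})")
write_genbank(construct, "construct.gb")
print("wrote construct.gb (GenBank flat file with the feature table above)")

try:
    sk.assemble_construct("AAA" + "GTCGAC" + "TTT", backbone)
except UniquenessError as err:
    print(f"\nplanted internal SalI site correctly rejected: {err}")
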