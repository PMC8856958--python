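"""Embedding guide duplexes into microRNA scaffold templates and assembling
full expression constructs.

Templates are data, not code: a :class:`ScaffoldTemplate` is an ordered
alternation of fixed nucleotide blocks and labelled slots (``sense_i``,
``antisense_i``), loadable from YAML so the shipped defaults can be
replaced by the user's own scaffold sequences.

Shipped defaults:

* ``MIRE_TEMPLATE`` — single-hairpin miR-E scaffold using the
  field-standard miR-E / miR-30a context (5' lower stem
  ``TGCTGTTGACAGTGAGCG``, loop ``TAGTGAAGCCACAGATGTA``, 3' lower stem
  ``TGCCTACTGCCTCGGA``...).
* ``MIR17_19B_TEMPLATE`` — a four-hairpin polycistron mimicking the
  mir17-19b cluster layout.  The real cluster's arm/loop sequences are
  replaced by synthetic stand-in arms (this template is a synthetic
  placeholder for desk-scale work; substitute real arms via YAML for
  cloning).

Restriction-site recognition sequences are configuration with standard
defaults (BsrGI TGTACA, AscI GGCGCGCC, SalI GTCGAC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import yaml

from .design import ConfigError, ContractError, MirEGuide
from .sequences import NucSequence, _validate_alphabet

__all__ = [
    "Segment",
    "ScaffoldTemplate",
    "BackboneSpec",
    "ConstructModel",
    "UniquenessError",
    "MIRE_TEMPLATE",
    "MIR17_19B_TEMPLATE",
    "DEFAULT_RESTRICTION_SITES",
    "embed_mirE",
    "embed_polycistron",
    "assemble_construct",
    "extract_slots",
    "template_from_yaml",
    "template_to_yaml",
    "write_genbank",
]

DEFAULT_RESTRICTION_SITES = {
    "BsrGI": "TGTACA",
    "AscI": "GGCGCGCC",
    "SalI": "GTCGAC",
}


@dataclass(frozen=True)
class Segment:
    """One template segment: either a fixed block (``seq`` set) or a
    labelled slot of declared length (``label``/``length`` set)."""

    kind: str  # "fixed" | "slot"
    seq: str = ""
    label: str = ""
    length: int = 0

    def __post_init__(self) -> None:
        if self.kind == "fixed":
            _validate_alphabet(self.seq)
        elif self.kind == "slot":
            if not self.label or self.length <= 0:
                raise ValueError("slot needs a label and a positive length")
        else:
            raise ValueError(f"unknown segment kind {self.kind!r}")


@dataclass
class ScaffoldTemplate:
    name: str
    segments: list[Segment]
    n_hairpins: int = 1

    def __post_init__(self) -> None:
        labels = [s.label for s in self.segments if s.kind == "slot"]
        if len(labels) != len(set(labels)):
            raise ValueError("slot labels must be unique")
        self.slot_labels = labels

    @property
    def fixed_length(self) -> int:
        return sum(len(s.seq) for s in self.segments if s.kind == "fixed")


def _fill(template: ScaffoldTemplate, values: dict[str, str]) -> str:
    parts = []
    for seg in template.segments:
        if seg.kind == "fixed":
            parts.append(seg.seq)
        else:
            try:
                v = values[seg.label]
            except KeyError:
                raise ContractError(f"no value supplied for slot {seg.label!r}")
            if len(v) != seg.length:
                raise ContractError(
                    f"slot {seg.label!r} expects {seg.length} nt, got {len(v)}"
                )
            _validate_alphabet(v)
            parts.append(v)
    return "".join(parts)


def embed_mirE(guide: MirEGuide, template: ScaffoldTemplate | None = None) -> str:
    """Substitute a 22/22 duplex into a single-hairpin mirE template.

    Output length is the template's fixed length plus 44.
    """
    template = template or MIRE_TEMPLATE
    if template.n_hairpins != 1:
        raise ContractError("embed_mirE requires a single-hairpin template")
    return _fill(template, {"sense_1": guide.sense22, "antisense_1": guide.antisense22})


def embed_polycistron(guides: Sequence[MirEGuide], template: ScaffoldTemplate | None = None) -> str:
    """Substitute four duplexes, in rank order, into a 4-hairpin template."""
    template = template or MIR17_19B_TEMPLATE
    if template.n_hairpins != 4:
        raise ContractError("polycistron template must declare 4 hairpins")
    if len(guides) != 4:
        raise ContractError(f"polycistron embedding needs exactly 4 guides, got {len(guides)}")
    values: dict[str, str] = {}
    for i, g in enumerate(guides, start=1):
        values[f"sense_{i}"] = g.sense22
        values[f"antisense_{i}"] = g.antisense22
    return _fill(template, values)


def extract_slots(template: ScaffoldTemplate, filled: str) -> dict[str, str]:
    """Recover slot contents from a filled scaffold (embedding inverse)."""
    out = {}
    pos = 0
    for seg in template.segments:
        if seg.kind == "fixed":
            if filled[pos : pos + len(seg.seq)] != seg.seq:
                raise ContractError(f"fixed block mismatch at position {pos}")
            pos += len(seg.seq)
        else:
            out[seg.label] = filled[pos : pos + seg.length]
            pos += seg.length
    if pos != len(filled):
        raise ContractError("filled sequence longer than template")
    return out


# ---------------------------------------------------------------------------
# construct assembly

class UniquenessError(ValueError):
    """A declared restriction flank site occurs more than once (or not at
    all) in the assembled construct; positions are listed in the message."""


@dataclass
class BackboneSpec:
    """Backbone declaration: promoter, ORF, where the 3'-UTR insert goes,
    and which restriction sites flank it."""

    promoter_name: str
    promoter_seq: str
    orf: NucSequence
    utr3_spacer: str = ""          # between ORF stop and the 5' flank sites
    flank5_sites: tuple[str, ...] = ("BsrGI", "AscI")
    flank3_sites: tuple[str, ...] = ("SalI",)
    utr3_remainder: str = ""       # backbone sequence 3' of the insert flank
    restriction_sites: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_RESTRICTION_SITES)
    )

    def with_orf(self, orf: NucSequence) -> "BackboneSpec":
        """Variant backbone with the ORF swapped (e.g. mCherry for
        hM4Di_CFP); flanks unchanged."""
        return BackboneSpec(
            promoter_name=self.promoter_name,
            promoter_seq=self.promoter_seq,
            orf=orf,
            utr3_spacer=self.utr3_spacer,
            flank5_sites=self.flank5_sites,
            flank3_sites=self.flank3_sites,
            utr3_remainder=self.utr3_remainder,
            restriction_sites=dict(self.restriction_sites),
        )


@dataclass
class ConstructModel:
    """An assembled expression construct with a GenBank-style feature
    table (name, type, 0-based half-open start/end)."""

    promoter: str
    orf: NucSequence
    utr3_insert: str
    flank_sites: dict[str, str]
    full_sequence: str
    features: list[tuple[str, str, int, int]]

    def feature(self, name: str) -> tuple[int, int]:
        for n, _t, s, e in self.features:
            if n == name:
                return (s, e)
        raise KeyError(name)


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def assemble_construct(insert: str, backbone: BackboneSpec) -> ConstructModel:
    """Concatenate promoter + ORF + 5' flank sites + insert + 3' flank
    sites + remainder and validate the result.

    Validation: every declared flank site occurs exactly once in the full
    sequence (an insert or backbone re-creating a site raises
    :class:`UniquenessError` listing all positions), and the insert starts
    strictly 3' of the ORF stop codon.
    """
    _validate_alphabet(insert)
    sites = backbone.restriction_sites
    for name in (*backbone.flank5_sites, *backbone.flank3_sites):
        if name not in sites:
            raise ConfigError(f"no recognition sequence configured for {name}")

    parts: list[tuple[str, str, str]] = [("promoter", backbone.promoter_name, backbone.promoter_seq)]
    parts.append(("ORF", backbone.orf.id, backbone.orf.seq))
    if backbone.utr3_spacer:
        parts.append(("misc", "utr3_spacer", backbone.utr3_spacer))
    for name in backbone.flank5_sites:
        parts.append(("restriction_site", name, sites[name]))
    parts.append(("scaffold_insert", "utr3_insert", insert))
    for name in backbone.flank3_sites:
        parts.append(("restriction_site", name, sites[name]))
    if backbone.utr3_remainder:
        parts.append(("misc", "utr3_remainder", backbone.utr3_remainder))

    features = []
    pos = 0
    for ftype, name, seq in parts:
        features.append((name, ftype, pos, pos + len(seq)))
        pos += len(seq)
    full = "".join(seq for _, _, seq in parts)

    problems = []
    for name in (*backbone.flank5_sites, *backbone.flank3_sites):
        hits = _find_all(full, sites[name])
        if len(hits) != 1:
            problems.append(f"{name} ({sites[name]}) occurs {len(hits)}x at {hits}")
    if problems:
        raise UniquenessError("; ".join(problems))

    orf_start, orf_end = next((s, e) for n, t, s, e in features if t == "ORF")
    ins_start, _ = next((s, e) for n, t, s, e in features if t == "scaffold_insert")
    if ins_start <= orf_end - 3:
        raise ValueError("insert must lie strictly 3' of the ORF stop codon")

    return ConstructModel(
        promoter=backbone.promoter_name,
        orf=backbone.orf,
        utr3_insert=insert,
        flank_sites={
            n: sites[n] for n in (*backbone.flank5_sites, *backbone.flank3_sites)
        },
        full_sequence=full,
        features=features,
    )


# ---------------------------------------------------------------------------
# YAML templates and GenBank output

def template_from_yaml(path) -> ScaffoldTemplate:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    segs = []
    for item in doc["segments"]:
        if "fixed" in item:
            segs.append(Segment("fixed", seq=item["fixed"].upper()))
        else:
            segs.append(Segment("slot", label=item["slot"], length=int(item.get("length", 22))))
    return ScaffoldTemplate(doc["name"], segs, n_hairpins=int(doc.get("n_hairpins", 1)))


def template_to_yaml(template: ScaffoldTemplate, path) -> None:
    doc = {
        "name": template.name,
        "n_hairpins": template.n_hairpins,
        "segments": [
            {"fixed": s.seq} if s.kind == "fixed" else {"slot": s.label, "length": s.length}
            for s in template.segments
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_genbank(construct: ConstructModel, path, name: str = "construct") -> None:
    """Write the construct as an annotated GenBank flat file."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    rec = SeqRecord(Seq(construct.full_sequence), id=name, name=name[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    type_map = {
        "promoter": "promoter",
        "ORF": "CDS",
        "scaffold_insert": "misc_feature",
        "restriction_site": "misc_feature",
        "misc": "misc_feature",
    }
    for fname, ftype, s, e in construct.features:
        rec.features.append(
            SeqFeature(
                FeatureLocation(s, e),
                type=type_map.get(ftype, "misc_feature"),
                qualifiers={"label": [fname]},
            )
        )
    SeqIO.write([rec], path, "genbank")


# ---------------------------------------------------------------------------
# default templates

def _hairpin_segments(i: int, arm5: str, loop: str, arm3: str) -> list[Segment]:
    return [
        Segment("fixed", seq=arm5),
        Segment("slot", label=f"sense_{i}", length=22),
        Segment("fixed", seq=loop),
        Segment("slot", label=f"antisense_{i}", length=22),
        Segment("fixed", seq=arm3),
    ]


#: Single-hairpin miR-E scaffold (standard miR-E/miR-30a context sequences).
MIRE_TEMPLATE = ScaffoldTemplate(
    "mirE",
    _hairpin_segments(
        1,
        arm5="TGCTGTTGACAGTGAGCG",
        loop="TAGTGAAGCCACAGATGTA",
        arm3="TGCCTACTGCCTCGGACTTCAAGGGGCTA",
    ),
    n_hairpins=1,
)

_MIRP_ARMS = [
    # synthetic stand-in arms; real mir17-19b cluster arms go here via YAML
    ("GGTCAGAATAATGTCAAAGTG", "GTTTTGGCCACTGACTGAC", "CAGGACACAAGGCCTGTTACT"),
    ("GATTCACCTTCTGAGAGTAGT", "GTGAAGCCACAGATGGGT", "ACTACACAAGGCTGAGTTGAA"),
    ("GGTGATTGTAGAACTATGTGC", "CTGTGAAGCCACAGATGGG", "GCACAAGTTAGGGTCTCAGGG"),
    ("GACCTATCCTGAATTGTCACG", "GTGAAGCCACAGATGTAC", "CGTGACAACTTGGAGTACTCA"),
]


def _mirp_segments() -> list[Segment]:
    segs: list[Segment] = [Segment("fixed", seq="GGATCCAAGG")]
    for i, (a5, loop, a3) in enumerate(_MIRP_ARMS, start=1):
        segs.extend(_hairpin_segments(i, a5, loop, a3))
        segs.append(Segment("fixed", seq="TCTAGACCGG"[: 8 + (i % 2)]))
    return segs


#: Four-hairpin polycistron mimicking the mir17-19b layout.  The arm/loop
#: sequences are a synthetic stand-in (see module docstring); structure
#: (hairpin count, slot order, spacers) follows the polycistronic design.
MIR17_19B_TEMPLATE = ScaffoldTemplate("mir17-19b", _mirp_segments(), n_hairpins=4)
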