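"""siRNA candidate enumeration, ranking, filtering, and transformation into
mirE-ready 22-nt duplexes.

The design pipeline mirrors how anti-target shRNAmir guides are built in
practice:

1. enumerate every 21-nt sense window on a reference isoform (the longest,
   by default), keeping only windows with 2 nt of upstream context;
2. rank the windows with a pluggable scoring strategy (external ranking
   tools such as DSIR can be injected as pre-computed scores; the built-in
   heuristic is a GC-content bonus plus a 5'-antisense thermodynamic
   asymmetry proxy);
3. discard windows whose 22-nt pre-mismatch target window is not shared
   verbatim by every known isoform of the target gene;
4. discard windows with more than 15 nt of contiguous complementarity to
   any non-target transcript (equivalently: windows sharing a 16-mer with
   the background transcriptome);
5. extend the surviving 21-mers to fully overlapping 22-nt duplexes and
   apply the single 5'-sense mismatch that mimics endogenous miR-30A
   processing.

All coordinates are 0-based half-open on the reference isoform.  The scan
operates on the sense (mRNA) strand of transcripts: the guide strand is
antisense to the mRNA, so "the guide has a k-nt run of complementarity to
transcript t" is exactly "the target sense window shares a k-mer with t".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import pandas as pd

from .sequences import (
    KmerIndex,
    NucSequence,
    Transcriptome,
    build_kmer_index,
    longest_common_substring,
    reverse_complement,
)

__all__ = [
    "ContractError",
    "ConfigError",
    "DesignConfig",
    "GuideCandidate",
    "MirEGuide",
    "OfftargetResult",
    "DesignResult",
    "enumerate_candidates",
    "rank_candidates",
    "check_isoform_coverage",
    "target_window22",
    "offtarget_scan",
    "make_mirE_duplex",
    "apply_sense_mismatch",
    "design_guides",
    "get_scorer",
]


class ContractError(ValueError):
    """An operation was called with an argument violating its contract."""


class ConfigError(ValueError):
    """Invalid design configuration (e.g. unknown scorer name)."""


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters of the design pipeline.

    ``seed_k`` must equal ``max_offtarget_complementarity + 1``: a window
    has a contiguous off-target run longer than the threshold iff it shares
    a (threshold+1)-mer with a non-target transcript.
    """

    guide_length: int = 21
    duplex_length: int = 22
    max_offtarget_complementarity: int = 15
    seed_k: int = 16
    n_select_mirE: int = 3
    n_select_polycistron: int = 4
    scorer: str = "heuristic"

    def __post_init__(self) -> None:
        if self.seed_k != self.max_offtarget_complementarity + 1:
            raise ConfigError(
                "seed_k must equal max_offtarget_complementarity + 1 "
                f"(got {self.seed_k} vs {self.max_offtarget_complementarity})"
            )
        if self.n_select_mirE < 1 or self.n_select_polycistron < 1:
            raise ConfigError("n_select_* must be >= 1")


@dataclass(frozen=True)
class GuideCandidate:
    """A 21-nt sense window on the reference isoform.

    ``sense21`` equals ``target[start:start+21)``; ``score`` is filled in by
    :func:`rank_candidates` (higher = better).
    """

    target_id: str
    start: int
    sense21: str
    score: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.sense21) != 21:
            raise ContractError(f"sense21 must be 21 nt, got {len(self.sense21)}")


@dataclass(frozen=True)
class MirEGuide:
    """A fully overlapping 22-nt sense/antisense duplex.

    ``sense22_raw`` is the unedited target window
    ``target[start-2:start+20)``; ``antisense22`` is its reverse complement
    (the guide strand); ``sense22`` carries the single first-position
    mismatch mimicking endogenous miR-30A processing.
    """

    sense22: str
    sense22_raw: str
    antisense22: str
    origin: GuideCandidate

    def __post_init__(self) -> None:
        if len(self.sense22) != 22 or len(self.sense22_raw) != 22 or len(self.antisense22) != 22:
            raise ContractError("duplex strands must all be 22 nt")
        if self.antisense22 != reverse_complement(self.sense22_raw):
            raise ContractError("antisense22 must be revcomp of sense22_raw")
        diffs = [i for i, (a, b) in enumerate(zip(self.sense22, self.sense22_raw)) if a != b]
        if diffs not in ([], [0]):
            raise ContractError("sense22 may differ from sense22_raw at position 0 only")


def enumerate_candidates(target: NucSequence, cfg: DesignConfig | None = None) -> list[GuideCandidate]:
    """Enumerate every admissible 21-nt sense window on ``target``.

    Admissible starts are ``[2, L-21]``: the later 22-mer extension needs
    2 nt of upstream context.  Windows touching an N (hard-masked base,
    when the sequence allows N) are skipped.  Targets shorter than 23 nt
    yield an empty list with a warning.
    """
    cfg = cfg or DesignConfig()
    L = len(target.seq)
    g = cfg.guide_length
    if L < g + 2:
        warnings.warn(f"target {target.id!r} shorter than {g + 2} nt; no candidates")
        return []
    out = []
    for start in range(2, L - g + 1):
        context = target.seq[start - 2 : start + g]
        if "N" in context:
            continue
        out.append(GuideCandidate(target.id, start, target.seq[start : start + g]))
    return out


# ---------------------------------------------------------------------------
# scoring

def _at_fraction(s: str) -> float:
    return sum(c in "AT" for c in s) / len(s)


def heuristic_score(candidate: GuideCandidate) -> float:
    """Default rank score: GC-window bonus + 5'-antisense asymmetry proxy.

    * +1 if the GC fraction of the 21-mer lies in [0.30, 0.65] (outside
      this band silencing efficacy drops);
    * plus the difference in A/T fraction between the last and first four
      sense bases.  The guide (antisense) 5' end pairs with the sense 3'
      end, and A/T-rich pairing there biases RISC towards loading the
      guide strand.
    """
    gc = sum(c in "GC" for c in candidate.sense21) / 21
    bonus = 1.0 if 0.30 <= gc <= 0.65 else 0.0
    asym = _at_fraction(candidate.sense21[-4:]) - _at_fraction(candidate.sense21[:4])
    return bonus + asym


def constant_score(candidate: GuideCandidate) -> float:
    return 0.0


_SCORERS: dict[str, Callable[[GuideCandidate], float]] = {
    "heuristic": heuristic_score,
    "constant": constant_score,
}


def get_scorer(
    scorer: str | Callable[[GuideCandidate], float],
    external_scores: Mapping[int, float] | None = None,
) -> Callable[[GuideCandidate], float]:
    """Resolve a scorer name or callable.

    ``"external"`` looks candidates up by start position in
    ``external_scores`` (e.g. pasted output of an external ranking tool).
    """
    if callable(scorer):
        return scorer
    if scorer == "external":
        if external_scores is None:
            raise ConfigError("external scorer requires external_scores mapping")
        scores = dict(external_scores)

        def _external(c: GuideCandidate) -> float:
            try:
                return float(scores[c.start])
            except KeyError:
                raise ConfigError(f"no external score for candidate at start {c.start}")

        return _external
    try:
        return _SCORERS[scorer]
    except KeyError:
        raise ConfigError(f"unknown scorer {scorer!r}; known: {sorted(_SCORERS)} or 'external'")


def rank_candidates(
    candidates: Sequence[GuideCandidate],
    scorer: str | Callable[[GuideCandidate], float] = "heuristic",
    external_scores: Mapping[int, float] | None = None,
) -> list[GuideCandidate]:
    """Score and sort candidates, best first.

    Descending score; ties broken by smaller start, then lexicographic
    sense21 — fully deterministic.
    """
    fn = get_scorer(scorer, external_scores)
    scored = [replace(c, score=float(fn(c))) for c in candidates]
    return sorted(scored, key=lambda c: (-c.score, c.start, c.sense21))


# ---------------------------------------------------------------------------
# filters

def target_window22(candidate: GuideCandidate, target: NucSequence) -> str:
    """The 22-nt pre-mismatch target window ``target[start-2, start+20)``."""
    if candidate.start < 2:
        raise ContractError("candidate start < 2: no upstream context for 22-mer")
    w = target.seq[candidate.start - 2 : candidate.start + 20]
    if len(w) != 22:
        raise ContractError("window extends past end of target")
    return w


def check_isoform_coverage(
    candidate: GuideCandidate,
    isoforms: Sequence[NucSequence],
    target: NucSequence,
) -> bool:
    """True iff the 22-nt pre-mismatch window occurs verbatim in every
    isoform — guides must hit all known isoforms of the target gene."""
    if not isoforms:
        raise ValueError("need at least one isoform")
    w = target_window22(candidate, target)
    return all(w in iso.seq for iso in isoforms)


@dataclass(frozen=True)
class OfftargetResult:
    passed: bool
    max_run: int | None = None


def offtarget_scan(
    candidate: GuideCandidate,
    index: KmerIndex,
    target: NucSequence,
    compute_max_run: bool = False,
) -> OfftargetResult:
    """Screen the 22-nt target window against the background index.

    Fails iff any length-k substring of the window occurs in a non-target
    transcript, i.e. iff the maximum contiguous complementarity exceeds
    k-1 (15 nt at the default seed length 16).  With
    ``compute_max_run=True`` the exact maximum run is measured against the
    indexed transcripts with the longest-common-substring routine.
    """
    w = target_window22(candidate, target)
    hit = any(index.query(w[i : i + index.k]) for i in range(len(w) - index.k + 1))
    max_run = None
    if compute_max_run:
        if index.transcripts:
            # '#' separators prevent runs spanning transcript boundaries
            blob = "#".join(t.seq for t in index.transcripts)
            max_run = longest_common_substring(w, blob)
        else:
            max_run = 0
    return OfftargetResult(passed=not hit, max_run=max_run)


# ---------------------------------------------------------------------------
# duplex construction

_MISMATCH = {"C": "A", "G": "A", "A": "C", "T": "C"}


def apply_sense_mismatch(sense22_raw: str) -> str:
    """Introduce the single 5'-sense mismatch (C/G -> A, A/T -> C).

    The edit mimics the bulge of endogenous miR-30A and touches position 0
    only; the guide strand is left perfectly complementary to the target.
    """
    if len(sense22_raw) != 22:
        raise ContractError(f"expected a 22-nt sense strand, got {len(sense22_raw)} nt")
    return _MISMATCH[sense22_raw[0]] + sense22_raw[1:]


def make_mirE_duplex(candidate: GuideCandidate, target: NucSequence) -> MirEGuide:
    """Extend a 21-nt candidate to the fully overlapping 22-nt mirE duplex.

    The sense strand drops one 3' base and gains the two upstream target
    bases (``target[start-2, start+20)``); the antisense strand is its
    exact reverse complement, so the duplex has no overhangs.  The
    mismatch rule is then applied to the sense strand.
    """
    raw = target_window22(candidate, target)
    return MirEGuide(
        sense22=apply_sense_mismatch(raw),
        sense22_raw=raw,
        antisense22=reverse_complement(raw),
        origin=candidate,
    )


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class DesignResult:
    """Selected guides plus a per-candidate audit of filter outcomes."""

    guides: list[MirEGuide]
    audit: pd.DataFrame
    reference_id: str

    def to_tsv(self, path) -> None:
        rows = []
        for rank, g in enumerate(self.guides, start=1):
            rows.append(
                {
                    "rank": rank,
                    "start": g.origin.start,
                    "sense21": g.origin.sense21,
                    "sense22": g.sense22,
                    "antisense22": g.antisense22,
                    "score": g.origin.score,
                    "filters_passed": "isoform_coverage,offtarget",
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def design_guides(
    target_isoforms: Sequence[NucSequence],
    transcriptome: Transcriptome,
    cfg: DesignConfig | None = None,
    n_select: int | None = None,
    scorer: str | Callable[[GuideCandidate], float] | None = None,
    external_scores: Mapping[int, float] | None = None,
    index: KmerIndex | None = None,
) -> DesignResult:
    """Run the full pipeline: enumerate -> rank -> filter -> top-n duplexes.

    The reference isoform for enumeration is the longest (first wins ties);
    the coverage filter then enforces presence in every isoform.  If fewer
    candidates survive than requested, the survivors are returned with a
    warning rather than an error.
    """
    cfg = cfg or DesignConfig()
    if not target_isoforms:
        raise ValueError("need at least one target isoform")
    n_select = n_select if n_select is not None else cfg.n_select_mirE
    reference = max(target_isoforms, key=lambda t: (len(t.seq),))
    if index is None:
        index = build_kmer_index(transcriptome)
    if index.k != cfg.seed_k:
        raise ConfigError(f"index k={index.k} != cfg.seed_k={cfg.seed_k}")

    candidates = enumerate_candidates(reference, cfg)
    ranked = rank_candidates(candidates, scorer or cfg.scorer, external_scores)

    audit_rows = []
    survivors = []
    for rank, c in enumerate(ranked, start=1):
        cov = check_isoform_coverage(c, target_isoforms, reference)
        off = offtarget_scan(c, index, reference) if cov else OfftargetResult(passed=False)
        ok = cov and off.passed
        audit_rows.append(
            {
                "rank": rank,
                "start": c.start,
                "sense21": c.sense21,
                "score": c.score,
                "isoform_coverage": cov,
                "offtarget_pass": bool(off.passed) if cov else None,
                "selected": False,
            }
        )
        if ok:
            survivors.append(c)
    audit = pd.DataFrame(audit_rows)
    chosen = survivors[:n_select]
    if len(chosen) < n_select:
        warnings.warn(
            f"only {len(chosen)} candidates survive filtering (requested {n_select})"
        )
    sel_starts = {c.start for c in chosen}
    if len(audit):
        audit["selected"] = audit["start"].isin(sel_starts)
    guides = [make_mirE_duplex(c, reference) for c in chosen]
    return DesignResult(guides=guides, audit=audit, reference_id=reference.id)
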