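"""Genome-wide hairpin candidate extraction and scoring.

Pipeline: split each chromosome into overlapping windows (500 nt, 250 nt
step), fold both strands, extract stem-loop elements (stem with >= 3
consecutive pairs enclosing a terminal loop of >= 3 nt), filter by hairpin
length [36, 180], remove duplicate sequences genome-wide, compute features,
apply the trained per-study models and ensemble rules, and report
candidates above the confidence threshold with BED-style coordinates
(0-based, half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from . import structure as st
from .datasets import MAX_HAIRPIN_LEN, MIN_HAIRPIN_LEN, HairpinRecord
from .ensemble import RuleDecision, average_predict, consensus_rule, consensus_vote

DEFAULT_WINDOW = 500
DEFAULT_STEP = 250
MIN_STEM_RUN = 3  # consecutive base pairs required of a hairpin stem
MIN_LOOP_NT = 3  # unpaired nucleotides required of the terminal loop

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GenomeFragment:
    chrom: str
    start: int  # 0-based half-open, + strand coordinates
    end: int
    strand: str  # '+' or '-'
    rna_seq: str


@dataclass
class CandidateHairpin:
    chrom: str
    start: int
    end: int
    strand: str
    hairpin: HairpinRecord
    scores: dict = field(default_factory=dict)
    avg_dt: float | None = None
    avg_nb: float | None = None
    decision: RuleDecision | None = None

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def fragment_genome(chromosomes: dict[str, str],
                    window: int = DEFAULT_WINDOW,
                    step: int = DEFAULT_STEP,
                    min_fragment: int = MIN_HAIRPIN_LEN) -> list[GenomeFragment]:
    """Overlapping + strand fragments of each chromosome.

    Fragments start at 0, step, 2*step, ...; a trailing fragment shorter
    than the window is kept when it is at least ``min_fragment`` long
    (otherwise the chromosome end would be invisible to the scanner).
    """
    if not window > step > 0:
        raise ValueError("require window > step > 0")
    frags = []
    for chrom, seq in chromosomes.items():
        n = len(seq)
        for start in range(0, n, step):
            end = min(start + window, n)
            if end - start >= min_fragment:
                frags.append(GenomeFragment(
                    chrom, start, end, "+",
                    st.normalize_rna(seq[start:end], ambiguous="map_to_a"),
                ))
    return frags


def to_rna_both_strands(dna_fragment: str) -> tuple[str, str]:
    """(+, -) strand RNA for a DNA fragment: T→U, and reverse complement
    then T→U for the template strand."""
    up = dna_fragment.upper()
    bad = sorted({c for c in up if c not in "ACGTN"})
    if bad:
        raise ValueError(f"non-ACGTN characters in DNA fragment: {bad}")
    plus = st.normalize_rna(up, ambiguous="map_to_a")
    minus = st.normalize_rna(
        str(Seq(up).reverse_complement()), ambiguous="map_to_a"
    )
    return plus, minus


def extract_hairpins(fold: st.FoldResult) -> list[tuple[str, str, int, int]]:
    """Stem-loop elements of a folded fragment.

    Each element contains exactly one terminal loop of >= 3 unpaired bases
    enclosed by a stem with >= 3 consecutive pairs.  Elements are maximal:
    from the loop-closing pair the stem is extended outward through bulges
    and internal loops until the enclosing structure branches or ends.
    Returns (subsequence, substructure, start, end) with 0-based half-open
    local offsets into the fragment.
    """
    pairs = st.parse_dotbracket(fold.structure)
    pt = st.pair_table(fold.structure)
    pair_set = set(pairs)
    out = []
    for i, j in sorted(pairs):
        # terminal-loop-closing pair: nothing paired strictly inside
        if any(pt[k] != -1 for k in range(i + 1, j)):
            continue
        if j - i - 1 < MIN_LOOP_NT:
            continue
        # extend outward while (a, b) remains the unique enclosing helix
        a, b = i, j
        while True:
            na, nb = a - 1, b + 1
            if na < 0 or nb >= len(pt):
                break
            # skip unpaired bases (bulges / internal loops) outward
            while na >= 0 and pt[na] == -1:
                na -= 1
            while nb < len(pt) and pt[nb] == -1:
                nb += 1
            if na < 0 or nb >= len(pt):
                break
            if pt[na] == nb:  # still the same nested helix
                a, b = na, nb
            else:  # branch point (multiloop) or unrelated helix
                break
        # stem quality: a run of >= 3 strictly consecutive pairs anywhere
        # within the extended element
        run_ok = any(
            all((p + t, q - t) in pair_set for t in range(MIN_STEM_RUN))
            for (p, q) in pair_set
            if a <= p and q <= b
        )
        if not run_ok:
            continue
        out.append((fold.sequence[a:b + 1], fold.structure[a:b + 1], a, b + 1))
    return out


@dataclass
class ScanSummary:
    n_fragments: int = 0
    n_hairpins_raw: int = 0
    n_hairpins_length_filtered: int = 0
    n_hairpins_deduped: int = 0
    n_candidates_reported: int = 0
    duplicate_loci: list = field(default_factory=list)


def scan(
    chromosomes: dict[str, str],
    models: dict | None = None,
    threshold: float | None = None,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_len: int = MIN_HAIRPIN_LEN,
    max_len: int = MAX_HAIRPIN_LEN,
    backend: str = "fallback",
) -> tuple[list[CandidateHairpin], ScanSummary]:
    """Run the full scan pipeline over ``chromosomes`` (name → DNA string).

    ``models`` maps (study, kind) → TrainedModel as produced by
    :meth:`MCCVResults.load_bundle`; with ``models=None`` the scan stops
    after extraction/filtering and reports unscored candidates.  With a
    threshold, only candidates whose Average_DT score (falling back to
    Average_NB when no DT models exist) reaches it are reported.
    """
    from . import features as ft

    feature_union: list[str] = []
    if models:
        for m in models.values():
            for n in m.feature_names:
                if n not in feature_union:
                    feature_union.append(n)
        unknown = [n for n in feature_union if n not in ft.REGISTRY]
        if unknown:  # fail fast before any folding work
            raise ValueError(f"bundle schema names unknown features: {unknown}")

    summary = ScanSummary()
    candidates: list[CandidateHairpin] = []
    for frag in fragment_genome(chromosomes, window, step, min_fragment=min_len):
        dna = frag.rna_seq.replace("U", "T")
        plus, minus = to_rna_both_strands(dna)
        for strand, rna in (("+", plus), ("-", minus)):
            fr = st.fold(rna, backend=backend)
            for subseq, substruct, lo, hi in extract_hairpins(fr):
                summary.n_hairpins_raw += 1
                if strand == "+":
                    gstart = frag.start + lo
                    gend = frag.start + hi
                else:  # local coords are on the reverse complement
                    gstart = frag.end - hi
                    gend = frag.end - lo
                sub_energy = float(-substruct.count("("))
                rec = HairpinRecord(
                    id=f"{frag.chrom}:{gstart}-{gend}({strand})",
                    seq=subseq, struct=substruct, energy=sub_energy,
                    source="genome_scan",
                )
                candidates.append(CandidateHairpin(
                    chrom=frag.chrom, start=gstart, end=gend,
                    strand=strand, hairpin=rec,
                ))
        summary.n_fragments += 1

    candidates = [
        c for c in candidates if min_len <= len(c.hairpin.seq) <= max_len
    ]
    summary.n_hairpins_length_filtered = len(candidates)

    # genome-wide dedup on sequence; keep first by (chrom, start, strand)
    candidates.sort(key=lambda c: (c.chrom, c.start, c.strand))
    seen: set[str] = set()
    deduped, dropped = [], []
    for c in candidates:
        if c.hairpin.seq in seen:
            dropped.append(c.id)
        else:
            seen.add(c.hairpin.seq)
            deduped.append(c)
    candidates = deduped
    summary.duplicate_loci = dropped
    summary.n_hairpins_deduped = len(candidates)

    if models and candidates:
        X = ft.compute_matrix(
            [c.hairpin for c in candidates],
            profile=ft.StudyProfile("bundle", tuple(feature_union),
                                    len(feature_union)),
            backend=backend,
        )
        scores = {
            key: m.predict_scores(X[list(m.feature_names)])
            for key, m in models.items()
        }
        kinds = sorted({k for _, k in models})
        for idx, cand in enumerate(candidates):
            cand.scores = {key: float(v[idx]) for key, v in scores.items()}
            per_kind_avg = {}
            for kind in kinds:
                vals = [cand.scores[(s, k)] for (s, k) in cand.scores if k == kind]
                per_kind_avg[kind], _ = average_predict(vals)
            cand.avg_dt = per_kind_avg.get("DT")
            cand.avg_nb = per_kind_avg.get("NB")
            if cand.avg_dt is not None and cand.avg_nb is not None:
                cand.decision = consensus_rule(cand.avg_dt, cand.avg_nb)
        if threshold is not None:
            def _score(c):
                return c.avg_dt if c.avg_dt is not None else c.avg_nb
            candidates = [c for c in candidates if _score(c) >= threshold]

    summary.n_candidates_reported = len(candidates)
    return candidates, summary


def consensus_votes_for(candidate: CandidateHairpin, kind: str,
                        threshold_votes: int = 7) -> str:
    """Majority-vote label for one candidate from its stored per-study
    scores of one classifier kind (score >= 0.5 counts as a positive vote)."""
    votes = [int(v >= 0.5) for (s, k), v in candidate.scores.items() if k == kind]
    return consensus_vote(votes, n_studies=len(votes),
                          threshold=threshold_votes)


def candidates_to_bed(candidates) -> list[tuple]:
    """BED6 rows; score = 1000 * average ensemble score (0 when unscored)."""
    rows = []
    for c in candidates:
        avg = c.avg_dt if c.avg_dt is not None else (c.avg_nb or 0.0)
        rows.append((c.chrom, c.start, c.end, c.id, 1000 * avg, c.strand))
    return rows


def candidates_to_table(candidates) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {"id": c.id, "chrom": c.chrom, "start": c.start, "end": c.end,
               "strand": c.strand, "length": len(c.hairpin.seq),
               "avg_dt": c.avg_dt, "avg_nb": c.avg_nb,
               "label": c.decision.label if c.decision else None,
               "rule_conflict": c.decision.rule_conflict if c.decision else None}
        for (s, k), v in c.scores.items():
            row[f"{s}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
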