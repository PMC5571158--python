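"""Synthetic inputs for building and testing the whole pipeline offline.

Three generators cover the data the real workflows consume:

* designed stem-loop sequences (positive-like) and shuffled/random
  sequences (negative-like), emulating the contrast between curated
  miRNA hairpins and pseudo-hairpin negatives;
* two Gaussian feature clouds with a controllable standardized separation
  between class means, for exercising the training/evaluation stack
  without folding anything;
* a synthetic chromosome with perfect hairpins planted at non-overlapping
  loci on random strands, plus the ground-truth intervals.

Everything is reproducible bit-for-bit from the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .datasets import MAX_HAIRPIN_LEN, MIN_HAIRPIN_LEN, Dataset, HairpinRecord

NUCLEOTIDES = np.array(list("ACGU"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic generators.

    ``separation`` is the distance between class means in pooled-SD units
    on every feature; ``stem_len``/``loop_len`` set hairpin geometry
    (defaults 20 bp GC-rich stem + 6 nt loop → 46 nt hairpins, well inside
    the [36, 180] length filter); ``gc_bias`` shifts background
    composition toward G/C.
    """

    seed: int = 0
    n_pos: int = 100
    n_neg: int = 100
    n_features: int = 10
    separation: float = 4.0
    stem_len: int = 20
    loop_len: int = 6
    gc_bias: float = 0.0
    genome_length: int = 10_000
    n_planted: int = 5

    def __post_init__(self):
        if min(self.n_pos, self.n_neg, self.n_features) < 0:
            raise ValueError("counts must be >= 0")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        hp_len = 2 * self.stem_len + self.loop_len
        if not MIN_HAIRPIN_LEN <= hp_len <= MAX_HAIRPIN_LEN:
            raise ValueError(
                f"hairpin geometry gives length {hp_len}, outside "
                f"[{MIN_HAIRPIN_LEN}, {MAX_HAIRPIN_LEN}]"
            )


_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _random_seq(rng: np.random.Generator, n: int, gc_bias: float = 0.0) -> str:
    gc = 0.25 + gc_bias / 2
    at = 0.25 - gc_bias / 2
    p = np.array([at, gc, gc, at])
    return "".join(rng.choice(NUCLEOTIDES, size=n, p=p / p.sum()))


def make_stemloop(rng: np.random.Generator, stem_len: int, loop_len: int,
                  gc_stem: bool = True) -> str:
    """One designed hairpin: 5' arm, unpaired A-loop, complementary 3' arm.

    A GC-only stem (default) folds unambiguously under maximum pairing;
    the all-A loop cannot pair with itself.
    """
    alphabet = np.array(list("GC")) if gc_stem else NUCLEOTIDES
    arm = "".join(rng.choice(alphabet, size=stem_len))
    loop = "A" * loop_len
    arm3 = "".join(_RNA_COMPLEMENT[c] for c in reversed(arm))
    return arm + loop + arm3


def make_hairpin_sequences(spec: FixtureSpec) -> tuple[Dataset, Dataset]:
    """(positive-like, negative-like) hairpin record sets.

    Positives are designed stem-loops (they fold into extractable
    hairpins under the fallback backend); negatives are per-record
    shuffles of the positives, preserving composition but destroying the
    designed complementarity.
    """
    rng = np.random.default_rng(spec.seed)
    pos = []
    for i in range(spec.n_pos):
        seq = make_stemloop(rng, spec.stem_len, spec.loop_len)
        pos.append(HairpinRecord(id=f"pos_{i}", seq=seq, label="positive",
                                 source="simulate"))
    neg = []
    for i in range(spec.n_neg):
        template = pos[i % len(pos)].seq if pos else _random_seq(
            rng, 2 * spec.stem_len + spec.loop_len, spec.gc_bias)
        chars = np.array(list(template))
        rng.shuffle(chars)
        neg.append(HairpinRecord(id=f"neg_{i}", seq="".join(chars),
                                 label="negative", source="simulate"))
    prov = [{"operation": "make_hairpin_sequences", "seed": spec.seed,
             "n_pos": spec.n_pos, "n_neg": spec.n_neg,
             "stem_len": spec.stem_len, "loop_len": spec.loop_len}]
    return (Dataset("sim_pos", pos, prov), Dataset("sim_neg", neg, prov))


def make_separable_features(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two unit-variance Gaussian clouds whose means differ by
    ``separation`` pooled SDs on every feature."""
    rng = np.random.default_rng(spec.seed)
    cols = [f"f{i}" for i in range(spec.n_features)]
    pos = rng.normal(loc=spec.separation, scale=1.0,
                     size=(spec.n_pos, spec.n_features))
    neg = rng.normal(loc=0.0, scale=1.0, size=(spec.n_neg, spec.n_features))
    pos_df = pd.DataFrame(pos, columns=cols,
                          index=[f"pos_{i}" for i in range(spec.n_pos)])
    neg_df = pd.DataFrame(neg, columns=cols,
                          index=[f"neg_{i}" for i in range(spec.n_neg)])
    return pos_df, neg_df


def make_synthetic_genome(
    spec: FixtureSpec,
) -> tuple[dict[str, str], list[tuple[str, int, int, str, int, str]]]:
    """A random DNA chromosome with perfect hairpins planted at
    non-overlapping loci on random strands.

    Returns (chromosomes dict, truth intervals as BED6 rows).  The planted
    element is the DNA transcription template whose RNA (on the chosen
    strand) is a designed stem-loop.
    """
    rng = np.random.default_rng(spec.seed)
    hp_len = 2 * spec.stem_len + spec.loop_len
    margin = hp_len + 10
    if spec.genome_length < spec.n_planted * 2 * margin:
        raise ValueError(
            f"genome of {spec.genome_length} nt cannot hold "
            f"{spec.n_planted} non-overlapping {hp_len} nt hairpins"
        )
    background = _random_seq(rng, spec.genome_length, spec.gc_bias).replace("U", "T")
    genome = list(background)
    placed: list[tuple[int, int]] = []
    truth = []
    attempts = 0
    while len(placed) < spec.n_planted:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("could not place all hairpins; spec overcrowded")
        start = int(rng.integers(0, spec.genome_length - hp_len))
        end = start + hp_len
        if any(s < end + 10 and start < e + 10 for s, e in placed):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        rna = make_stemloop(rng, spec.stem_len, spec.loop_len)
        dna = rna.replace("U", "T")
        if strand == "-":
            dna = str(Seq(dna).reverse_complement())
        genome[start:end] = list(dna)
        placed.append((start, end))
        truth.append(("chrSim", start, end, f"planted_{len(placed) - 1}",
                      0, strand))
    truth.sort(key=lambda t: t[1])
    return {"chrSim": "".join(genome)}, truth
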