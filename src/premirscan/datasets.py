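"""Hairpin data sets: records, filters, and the synthetic negative/positive
construction procedures (Shuffled, NotBestFold, and the feature-space
FR / BQ / AM samplers).

Every constructed :class:`Dataset` carries a provenance log (operation,
parameters, seed) sufficient to regenerate it bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import structure as st

# length bounds of human stem-loops observed in miRBase; used as the default
# hairpin length filter throughout the package
MIN_HAIRPIN_LEN = 36
MAX_HAIRPIN_LEN = 180
DEFAULT_MIN_RPM = 100.0
FEATURE_SPACE_N = 5000  # default size of FR/BQ/AM sampled sets


@dataclass
class HairpinRecord:
    """One candidate hairpin with optional structure, energy and metadata."""

    id: str
    seq: str
    struct: str | None = None
    energy: float | None = None
    label: str = "unlabeled"  # positive | negative | unlabeled
    rpm: float | None = None
    source: str = ""

    def __post_init__(self):
        self.seq = st.normalize_rna(self.seq)
        if (self.struct is None) != (self.energy is None):
            raise ValueError(f"{self.id}: struct and energy must be set together")
        if self.struct is not None and len(self.struct) != len(self.seq):
            raise ValueError(f"{self.id}: structure/sequence length mismatch")

    def folded(self, backend: str = "fallback") -> "HairpinRecord":
        """Return a copy with structure/energy filled in (no-op if present)."""
        if self.struct is not None:
            return self
        fr = st.fold(self.seq, backend=backend)
        return dataclasses.replace(self, struct=fr.structure, energy=fr.energy)


@dataclass
class Dataset:
    name: str
    records: list[HairpinRecord]
    provenance: list[dict] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def dedup_identical(records: list[HairpinRecord]) -> list[HairpinRecord]:
    """Drop records whose sequence string was already seen (first kept)."""
    seen: set[str] = set()
    out = []
    for r in records:
        if r.seq not in seen:
            seen.add(r.seq)
            out.append(r)
    return out


def filter_by_length(
    records, min_len: int = MIN_HAIRPIN_LEN, max_len: int = MAX_HAIRPIN_LEN
):
    """Keep records with min_len <= len(seq) <= max_len (inclusive bounds)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in records if min_len <= len(r.seq) <= max_len]


def filter_by_rpm(records, min_rpm: float = DEFAULT_MIN_RPM):
    """Keep records with reads-per-million >= min_rpm; all records must carry
    RPM metadata."""
    missing = [r.id for r in records if r.rpm is None]
    if missing:
        raise ValueError(f"records missing rpm metadata: {missing}")
    return [r for r in records if r.rpm >= min_rpm]


def make_shuffled(
    records: list[HairpinRecord], seed: int, preserve_dinucleotides: bool = False
) -> Dataset:
    """Negative set built by shuffling each sequence's residues.

    The default is a uniform mononucleotide permutation (seeded); the
    dinucleotide-preserving alternative performs a random Eulerian-walk
    shuffle that keeps every overlapping dinucleotide count intact.
    Either way the nucleotide multiset of each record is preserved exactly
    and hairpin ids gain a ``_shuf`` suffix.
    """
    rng = np.random.default_rng(seed)
    out = []
    for r in records:
        if preserve_dinucleotides:
            shuffled = _dinucleotide_shuffle(r.seq, rng)
        else:
            chars = np.array(list(r.seq))
            rng.shuffle(chars)
            shuffled = "".join(chars)
        out.append(
            HairpinRecord(
                id=f"{r.id}_shuf", seq=shuffled, label="negative", source="Shuffled"
            )
        )
    prov = [{
        "operation": "make_shuffled", "seed": seed,
        "preserve_dinucleotides": preserve_dinucleotides, "n_input": len(records),
    }]
    return Dataset("Shuffled", out, prov)


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson style shuffle preserving dinucleotide counts."""
    if len(seq) < 3:
        return seq
    # multigraph of nucleotide transitions; walk from seq[0] to seq[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for _ in range(64):  # rejection-sample a valid Eulerian ordering
        trial = {k: list(v) for k, v in edges.items()}
        for v in trial.values():
            rng.shuffle(v)
        walk = [seq[0]]
        node = seq[0]
        ok = True
        for _step in range(len(seq) - 1):
            nxt_list = trial.get(node)
            if not nxt_list:
                ok = False
                break
            node = nxt_list.pop(0)
            walk.append(node)
        if ok:
            return "".join(walk)
    return seq  # degenerate composition; identity is a valid shuffle


def make_notbestfold(
    records: list[HairpinRecord], backend: str = "fallback"
) -> Dataset:
    """Negative set pairing each sequence with its best *suboptimal* fold.

    Sequences are unchanged; each record's structure is the highest-ranked
    structure different from the optimal fold.  Records admitting no
    alternative structure are skipped and listed in the provenance log.
    """
    out, skipped = [], []
    for r in records:
        alts = st.subopt_fold(r.seq, k=1, backend=backend)
        if not alts:
            skipped.append(r.id)
            continue
        alt = alts[0]
        out.append(
            HairpinRecord(
                id=f"{r.id}_nbf", seq=r.seq, struct=alt.structure,
                energy=alt.energy, label="negative", source="NotBestFold",
            )
        )
    prov = [{
        "operation": "make_notbestfold", "backend": backend,
        "n_input": len(records), "skipped": skipped,
    }]
    return Dataset("NotBestFold", out, prov)


def quantile(values, q: float) -> float:
    """Shared quantile estimator (linear interpolation between order
    statistics); every module that needs quartiles uses this one."""
    return float(np.quantile(np.asarray(values, dtype=float), q, method="linear"))


_MODE_BOUNDS = {"FR": (0.0, 1.0), "BQ": (0.25, 0.75), "AM": (0.40, 0.60)}


def make_feature_space_set(
    matrix: pd.DataFrame, mode: str, n: int = FEATURE_SPACE_N, seed: int = 0
) -> pd.DataFrame:
    """Sample a synthetic data set directly in feature space.

    Per feature, values are drawn independently and uniformly between two
    quantiles of the input matrix's column: full range (min-max) for ``FR``,
    lower-upper quartile for ``BQ``, and the 40th-60th percentile for
    ``AM``.  Row ids are ``<mode>_<i>``.
    """
    if matrix.empty:
        raise ValueError("input feature matrix is empty")
    if mode not in _MODE_BOUNDS:
        raise ValueError(f"mode must be one of {sorted(_MODE_BOUNDS)}, got {mode!r}")
    lo_q, hi_q = _MODE_BOUNDS[mode]
    rng = np.random.default_rng(seed)
    lo = np.array([quantile(matrix[c], lo_q) for c in matrix.columns])
    hi = np.array([quantile(matrix[c], hi_q) for c in matrix.columns])
    values = lo + rng.random((n, len(matrix.columns))) * (hi - lo)
    index = [f"{mode}_{i}" for i in range(n)]
    out = pd.DataFrame(values, columns=matrix.columns, index=index)
    out.attrs["provenance"] = {
        "operation": "make_feature_space_set", "mode": mode, "n": n, "seed": seed,
    }
    return out
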