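"""Hairpin feature extraction.

Features fall into the four families used throughout the ab initio
pre-miRNA detection literature — sequence composition, sequence/structure
triplets, structural descriptors, and thermodynamic indices — plus a
probability family that requires a partition-function-capable backend.
The registry documents every feature; per-study selection profiles map the
13 published detection approaches onto reconstructed feature subsets.

Conventions fixed here and used consistently package-wide:

* GC% in MFEI1 is a percentage (50.0, not 0.5).
* A *stem* is a maximal run of >= 3 consecutive base pairs
  ((i,j), (i+1,j-1), ...); a *loop* is a maximal run of unpaired bases.
* Zero denominators make the affected index 0 (guarded, flagged in the
  schema description).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from . import structure as st
from .datasets import HairpinRecord

NUCLEOTIDES = "ACGU"

#: capabilities provided by each folding backend
BACKEND_CAPABILITIES = {
    "fallback": {"mfe"},
    "rnafold": {"mfe"},
}


@dataclass(frozen=True)
class FeatureDefinition:
    name: str
    group: str  # SEQ | TRIPLET | STRUCT | THERMO | PROB
    requires_backend: str  # none | mfe | partition_function
    description: str


class CapabilityError(RuntimeError):
    """A requested feature needs a backend capability that is unavailable."""


# ---------------------------------------------------------------------------
# feature family implementations
# ---------------------------------------------------------------------------

def seq_composition(seq: str) -> dict[str, float]:
    """22 sequence features: 4 mononucleotide and 16 overlapping
    dinucleotide frequencies, GC fraction, and length."""
    seq = st.normalize_rna(seq)
    n = len(seq)
    if n < 2:
        raise ValueError("sequence composition needs length >= 2")
    out: dict[str, float] = {}
    for nt in NUCLEOTIDES:
        out[f"freq_{nt}"] = seq.count(nt) / n
    di_counts = {a + b: 0 for a in NUCLEOTIDES for b in NUCLEOTIDES}
    for a, b in zip(seq, seq[1:]):
        di_counts[a + b] += 1
    for di, c in di_counts.items():
        out[f"freq_{di}"] = c / (n - 1)
    out["gc_fraction"] = (seq.count("G") + seq.count("C")) / n
    out["length"] = float(n)
    return out


TRIPLET_NAMES = [
    f"triplet_{''.join(s)}_{nt}"
    for s in product("(.", repeat=3)
    for nt in NUCLEOTIDES
]


def triplet_features(seq: str, struct: str) -> dict[str, float]:
    """32 triplet frequencies: paired-status of three consecutive positions
    combined with the centre nucleotide.

    Both bracket characters map to the paired symbol '(' before windowing,
    so a triplet key is e.g. ``"((." + centre A``.  Frequencies are
    normalised by the number of interior positions (L - 2) and sum to 1.
    """
    seq = st.normalize_rna(seq)
    if len(seq) != len(struct):
        raise ValueError("sequence/structure length mismatch")
    if len(seq) < 3:
        raise ValueError("triplet features need length >= 3")
    bad = sorted({c for c in struct} - set("(.)"))
    if bad:
        raise ValueError(f"invalid structure characters {bad}")
    # windows only need paired/unpaired status, so partial structures are
    # acceptable here; both brackets collapse to the paired symbol
    mapped = struct.replace(")", "(")
    counts = dict.fromkeys(TRIPLET_NAMES, 0)
    for i in range(1, len(seq) - 1):
        counts[f"triplet_{mapped[i - 1:i + 2]}_{seq[i]}"] += 1
    denom = len(seq) - 2
    return {k: v / denom for k, v in counts.items()}


_PAIR_CLASS = {
    frozenset("AU"): "AU", frozenset("GC"): "GC", frozenset("GU"): "GU",
}


def struct_features(seq: str, struct: str) -> dict[str, float]:
    """Structural descriptors derived from the dot-bracket string."""
    seq = st.normalize_rna(seq)
    pairs = sorted(st.parse_dotbracket(struct))
    L = len(struct)
    n_bp = len(pairs)
    out: dict[str, float] = {
        "n_bp": float(n_bp),
        "paired_fraction": 2 * n_bp / L,
        "dP": n_bp / L,
    }
    # terminal loop: unpaired stretch enclosed by the innermost pair of the
    # first hairpin loop (0 when the structure has no pair)
    pt = st.pair_table(struct)
    loop_len = 0
    for i, j in pairs:
        if all(pt[k] == -1 for k in range(i + 1, j)):
            loop_len = j - i - 1
            break
    out["terminal_loop_len"] = float(loop_len)
    # longest run of consecutive (stacked) pairs, and stems (runs >= 3)
    pair_set = set(pairs)
    runs = []
    for i, j in pairs:
        if (i - 1, j + 1) not in pair_set:  # run start
            k = 0
            while (i + k, j - k) in pair_set:
                k += 1
            runs.append(k)
    out["longest_pair_run"] = float(max(runs, default=0))
    out["n_stems"] = float(sum(1 for r in runs if r >= 3))
    # loops: maximal unpaired runs
    n_loops = 0
    in_loop = False
    for c in struct:
        if c == ".":
            if not in_loop:
                n_loops += 1
            in_loop = True
        else:
            in_loop = False
    out["n_loops"] = float(n_loops)
    # base-pair identity
    counts = {"AU": 0, "GC": 0, "GU": 0}
    for i, j in pairs:
        cls = _PAIR_CLASS.get(frozenset((seq[i], seq[j])))
        if cls:
            counts[cls] += 1
    for cls, c in counts.items():
        out[f"n_{cls.lower()}_pairs"] = float(c)
        out[f"frac_{cls.lower()}_pairs"] = c / n_bp if n_bp else 0.0
    return out


def thermo_features(seq: str, struct: str, energy: float) -> dict[str, float]:
    """Folding-energy indices: MFE, dG = MFE/L and the MFEI family.

    MFEI1 = dG / GC% (GC content as a percentage), MFEI2 = dG / n_stems,
    MFEI3 = dG / n_loops, MFEI4 = MFE / n_bp.  Zero denominators yield 0.
    """
    seq = st.normalize_rna(seq)
    L = len(seq)
    sf = struct_features(seq, struct)
    gc_pct = 100.0 * (seq.count("G") + seq.count("C")) / L
    dG = energy / L
    def _div(a, b):
        return a / b if b else 0.0
    return {
        "mfe": float(energy),
        "dG": dG,
        "mfei1": _div(dG, gc_pct),
        "mfei2": _div(dG, sf["n_stems"]),
        "mfei3": _div(dG, sf["n_loops"]),
        "mfei4": _div(energy, sf["n_bp"]),
    }


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _build_registry() -> dict[str, FeatureDefinition]:
    defs: list[FeatureDefinition] = []
    for nt in NUCLEOTIDES:
        defs.append(FeatureDefinition(
            f"freq_{nt}", "SEQ", "none", f"frequency of {nt} (count/L)"))
    for a in NUCLEOTIDES:
        for b in NUCLEOTIDES:
            defs.append(FeatureDefinition(
                f"freq_{a}{b}", "SEQ", "none",
                f"overlapping dinucleotide {a}{b} frequency (count/(L-1))"))
    defs.append(FeatureDefinition(
        "gc_fraction", "SEQ", "none", "(G+C)/L as a fraction in [0,1]"))
    defs.append(FeatureDefinition("length", "SEQ", "none", "sequence length L"))
    for name in TRIPLET_NAMES:
        trip, nt = name.split("_")[1], name.split("_")[2]
        defs.append(FeatureDefinition(
            name, "TRIPLET", "mfe",
            f"frequency of paired-status triple '{trip}' with centre {nt}, "
            "normalised by L-2"))
    struct_descr = {
        "n_bp": "number of base pairs",
        "paired_fraction": "2*n_bp/L",
        "dP": "base-pair density n_bp/L",
        "terminal_loop_len": "unpaired length of the first terminal loop",
        "longest_pair_run": "longest run of stacked pairs",
        "n_stems": "maximal runs of >= 3 consecutive pairs",
        "n_loops": "maximal unpaired runs",
        "n_au_pairs": "A-U pair count", "frac_au_pairs": "A-U pairs / n_bp (0 if none)",
        "n_gc_pairs": "G-C pair count", "frac_gc_pairs": "G-C pairs / n_bp (0 if none)",
        "n_gu_pairs": "G-U pair count", "frac_gu_pairs": "G-U pairs / n_bp (0 if none)",
    }
    for name, d in struct_descr.items():
        defs.append(FeatureDefinition(name, "STRUCT", "mfe", d))
    thermo_descr = {
        "mfe": "folding energy (kcal/mol thermodynamic backends; "
               "-(pair count) surrogate under the fallback backend)",
        "dG": "MFE/L",
        "mfei1": "dG / GC% with GC content as a percentage (0 if GC%=0)",
        "mfei2": "dG / n_stems (0 if no stems)",
        "mfei3": "dG / n_loops (0 if no loops)",
        "mfei4": "MFE / n_bp (0 if no pairs)",
    }
    for name, d in thermo_descr.items():
        defs.append(FeatureDefinition(name, "THERMO", "mfe", d))
    for name, d in {
        "mean_bp_probability": "mean equilibrium base-pair probability",
        "positional_entropy": "mean positional structure entropy",
    }.items():
        defs.append(FeatureDefinition(name, "PROB", "partition_function", d))
    return {fd.name: fd for fd in defs}


REGISTRY: dict[str, FeatureDefinition] = _build_registry()


def registry_names(groups=("SEQ", "TRIPLET", "STRUCT", "THERMO")) -> list[str]:
    """Registry feature names in deterministic order, filtered by group."""
    return [n for n, fd in REGISTRY.items() if fd.group in groups]


# ---------------------------------------------------------------------------
# per-study profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyProfile:
    """A published study's feature selection, reconstructed from the core
    registry.  ``declared_count`` records the feature count the study
    reported; when the reconstruction differs in size the profile is a
    documented approximation (``exact=False``)."""

    study: str
    feature_names: tuple[str, ...]
    declared_count: int

    def __post_init__(self):
        missing = [n for n in self.feature_names if n not in REGISTRY]
        if missing:
            raise ValueError(f"profile {self.study}: unknown features {missing}")

    @property
    def count_matches(self) -> bool:
        """True when the reconstruction has the study's declared size."""
        return len(self.feature_names) == self.declared_count


_SEQ = [n for n in REGISTRY if REGISTRY[n].group == "SEQ"]
_TRIPLET = TRIPLET_NAMES
_STRUCT = [n for n in REGISTRY if REGISTRY[n].group == "STRUCT"]
_THERMO = [n for n in REGISTRY if REGISTRY[n].group == "THERMO"]
_DINUC = [n for n in _SEQ if len(n) == 7]  # freq_XY
_CORE = ["gc_fraction", "length", "n_bp", "dP", "paired_fraction",
         "terminal_loop_len", "longest_pair_run", "n_stems", "n_loops",
         "mfe", "dG", "mfei1", "mfei2", "mfei3", "mfei4"]


def _profile(study, names, declared):
    # preserve order, drop duplicates
    uniq = list(dict.fromkeys(names))
    return StudyProfile(study, tuple(uniq), declared)


#: the 13 published ab initio detection studies and their reconstructed
#: feature selections (declared counts from the literature survey)
STUDY_PROFILES: dict[str, StudyProfile] = {
    p.study: p
    for p in [
        # the triplet family is the one published selection that is exactly
        # recoverable; the remaining profiles are documented reconstructions
        _profile("Xue", _TRIPLET, 32),
        _profile("Jiang", _TRIPLET + ["mfe", "dG"], 34),
        _profile("Ng", _DINUC + _CORE[:13], 29),
        _profile("Batuwita", _DINUC + ["dG", "mfei1", "mfei4", "dP",
                                       "terminal_loop_len"], 21),
        _profile("Xu", _TRIPLET + ["gc_fraction", "dG", "mfei1"], 35),
        _profile("Ding", _TRIPLET, 32),
        _profile("Chen", _SEQ + _TRIPLET + _STRUCT + _THERMO, 99),
        _profile("Burgt", _CORE + ["freq_A", "freq_C", "freq_G"], 18),
        _profile("Gudys", _DINUC + _CORE[:12], 28),
        _profile("Ritchie", _DINUC + _CORE + ["freq_A", "freq_C", "freq_G",
                                              "freq_U", "frac_gc_pairs"], 36),
        _profile("Bentwich", _CORE + _STRUCT, 26),
        _profile("Lopes", _CORE[2:], 13),
        _profile("Gao", _DINUC + _TRIPLET[:26] + _CORE, 57),
    ]
}

STUDY_NAMES: tuple[str, ...] = tuple(STUDY_PROFILES)


def full_profile() -> StudyProfile:
    """Profile selecting every feature computable without a partition
    function (the package's default training input)."""
    names = tuple(registry_names())
    return StudyProfile("full", names, len(names))


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def compute_features(record: HairpinRecord, backend: str = "fallback") -> dict:
    rec = record.folded(backend=backend)
    out = seq_composition(rec.seq)
    out.update(triplet_features(rec.seq, rec.struct))
    out.update(struct_features(rec.seq, rec.struct))
    out.update(thermo_features(rec.seq, rec.struct, rec.energy))
    return out


def compute_matrix(
    records,
    profile: StudyProfile | None = None,
    backend: str = "fallback",
) -> pd.DataFrame:
    """Feature matrix (rows = hairpin ids, columns = profile order).

    Features whose backend requirement exceeds the selected backend's
    capabilities raise :class:`CapabilityError` up front; the resulting
    matrix is guaranteed NaN/Inf-free.
    """
    if profile is None:
        profile = full_profile()
    caps = BACKEND_CAPABILITIES[backend]
    blocked = [
        n for n in profile.feature_names
        if REGISTRY[n].requires_backend not in ("none", *caps)
    ]
    if blocked:
        raise CapabilityError(
            f"features {blocked} require capabilities unavailable under "
            f"backend {backend!r}"
        )
    cols = list(profile.feature_names)
    rows = {}
    for r in records:
        vals = compute_features(r, backend=backend)
        rows[r.id] = [vals[c] for c in cols]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols, dtype=float)
    if not df.empty and not np.isfinite(df.to_numpy()).all():
        bad = df.columns[~np.isfinite(df.to_numpy()).all(axis=0)].tolist()
        raise FloatingPointError(f"non-finite feature values in columns {bad}")
    df.attrs["profile"] = profile.study
    return df


def schema(profile: StudyProfile | None = None) -> list[dict]:
    """JSON-ready schema rows for a profile (name, group, backend, description)."""
    if profile is None:
        profile = full_profile()
    return [
        {
            "name": n,
            "group": REGISTRY[n].group,
            "requires_backend": REGISTRY[n].requires_backend,
            "description": REGISTRY[n].description,
        }
        for n in profile.feature_names
    ]
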