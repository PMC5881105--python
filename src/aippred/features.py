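"""Fixed-length feature encodings for peptide sequences.

Five encoders, each mapping one peptide to a fixed-length named vector:

========  ======  ===================================================
encoder   length  meaning
========  ======  ===================================================
``aac``   20      amino acid composition: per-residue fraction
``aai``   20      composition weighted by averaged high-quality
                  AAindex physicochemical scales
``dpc``   400     dipeptide composition over ordered residue pairs
``ctd``   147     composition/transition/distribution descriptors for
                  seven physicochemical attributes (7 x 21)
``pcp``   9       global physicochemical properties (hydropathy and
                  charge fractions, molecular weight, aliphatic index)
========  ======  ===================================================

The hybrid encoding concatenates any subset in the fixed order
AAC, AAI, DPC, CTD, PCP (full length 20+20+400+147+9 = 596).

Feature names follow a fixed, documented scheme (``AAC_A``, ``DPC_AC``,
``CTD_hydrophobicity_T_12``, ``PCP_aliphatic_index``) so that importance
tables and model bundles are portable across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib.resources import files as _pkg_files
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParameterError, SequenceError
from .seqio import AMINO_ACIDS, PeptideDataset, validate_sequence

#: Version tag embedded in model bundles; bumped whenever any encoder's
#: output (values, names, or order) changes incompatibly.
ENCODER_VERSION = "1.0"

#: The 400 ordered dipeptides in lexicographic order AA, AC, ..., YY.
DIPEPTIDES: tuple[str, ...] = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_DP_INDEX = {dp: i for i, dp in enumerate(DIPEPTIDES)}

ENCODER_LENGTHS = {"aac": 20, "aai": 20, "dpc": 400, "ctd": 147, "pcp": 9}
HYBRID_ORDER = ("aac", "aai", "dpc", "ctd", "pcp")


@dataclass
class FeatureVector:
    """An ordered, named, finite real-valued feature vector."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.shape[0]:
            raise ParameterError("feature names and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("non-finite feature value")

    def __len__(self) -> int:
        return len(self.names)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


@dataclass
class FeatureMatrix:
    """Peptide-by-feature matrix with row ids and unique column names."""

    peptide_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.peptide_ids), len(self.feature_names)):
            raise ParameterError("matrix shape does not match ids/names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ParameterError("duplicate feature names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.peptide_ids, columns=self.feature_names
        )

    def write_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("id\t" + "\t".join(self.feature_names) + "\n")
            for pid, row in zip(self.peptide_ids, self.values):
                fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy(float))


# ---------------------------------------------------------------------------
# bundled constant tables
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return _pkg_files("aippred") / "data" / name


@lru_cache(maxsize=1)
def load_aaindex_tables() -> pd.DataFrame:
    """The eight bundled AAindex scales, residues x indices (raw values)."""
    df = pd.read_csv(_data_path("aaindex_high_quality.tsv"), sep="\t", comment="#")
    df = df.set_index("residue")
    if sorted(df.index) != sorted(AMINO_ACIDS) or df.shape[1] != 8:
        raise ConfigurationError("aaindex table must be 20 residues x 8 indices")
    return df.loc[list(AMINO_ACIDS)]


@lru_cache(maxsize=1)
def mean_normalized_index() -> np.ndarray:
    """Mean over the 8 scales of their per-scale min-max normalization.

    Each scale is normalized to [0,1] over the 20 residues before averaging
    so that no single scale's units dominate; the result is one value per
    residue, in alphabetical residue order.
    """
    raw = load_aaindex_tables().to_numpy(float)
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    return ((raw - lo) / (hi - lo)).mean(axis=1)


#: Fixed attribute order of the seven CTD property schemes.
CTD_PROPERTIES = (
    "hydrophobicity",
    "vdw_volume",
    "polarity",
    "polarizability",
    "charge",
    "secondary_structure",
    "solvent_accessibility",
)


@lru_cache(maxsize=1)
def load_ctd_schemes() -> dict[str, dict[str, int]]:
    """Per property, a residue -> group (1..3) map; groups partition the 20."""
    df = pd.read_csv(_data_path("ctd_groups.tsv"), sep="\t", comment="#")
    schemes: dict[str, dict[str, int]] = {}
    for prop in CTD_PROPERTIES:
        sub = df[df["property"] == prop]
        mapping: dict[str, int] = {}
        for _, row in sub.iterrows():
            for aa in row["residues"]:
                if aa in mapping:
                    raise ConfigurationError(f"CTD {prop}: residue {aa} in two groups")
                mapping[aa] = int(row["group"])
        if sorted(mapping) != sorted(AMINO_ACIDS):
            raise ConfigurationError(f"CTD {prop}: groups must cover all 20 residues")
        schemes[prop] = mapping
    return schemes


@lru_cache(maxsize=1)
def load_residue_masses() -> dict[str, float]:
    df = pd.read_csv(_data_path("residue_masses.tsv"), sep="\t", comment="#")
    masses = dict(zip(df["residue"], df["average_mass"].astype(float)))
    if sorted(masses) != sorted(AMINO_ACIDS):
        raise ConfigurationError("residue mass table must cover all 20 residues")
    return masses


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------


def encode_aac(sequence: str) -> FeatureVector:
    """Amino acid composition: fraction of each residue (sums to 1)."""
    sequence = validate_sequence(sequence)
    counts = np.zeros(20)
    for ch in sequence:
        counts[_AA_INDEX[ch]] += 1
    names = [f"AAC_{aa}" for aa in AMINO_ACIDS]
    return FeatureVector(names, counts / len(sequence))


def encode_dpc(sequence: str, denominator: str = "length") -> FeatureVector:
    """Dipeptide composition over the 400 ordered pairs.

    ``denominator="length"`` (default) divides the count of each dipeptide by
    the number of overlapping dipeptides in the sequence (L-1), so the vector
    sums to 1. ``denominator="constant"`` divides by 400 instead, a uniform
    rescaling kept as a configuration option.
    """
    sequence = validate_sequence(sequence)
    if denominator not in ("length", "constant"):
        raise ParameterError(f"unknown dpc denominator {denominator!r}")
    counts = np.zeros(400)
    for i in range(len(sequence) - 1):
        counts[_DP_INDEX[sequence[i : i + 2]]] += 1
    denom = (len(sequence) - 1) if denominator == "length" else 400.0
    names = [f"DPC_{dp}" for dp in DIPEPTIDES]
    return FeatureVector(names, counts / denom)


def encode_aai(sequence: str) -> FeatureVector:
    """Composition weighted by the averaged normalized AAindex scales.

    feature(i) = AAC(i) x mean normalized index value of residue i, giving a
    20-dimensional, length-independent vector with every entry in [0, 1].
    """
    aac = encode_aac(sequence)
    avg = mean_normalized_index()
    names = [f"AAI_{aa}" for aa in AMINO_ACIDS]
    return FeatureVector(names, aac.values * avg)


def _ctd_distribution(positions: list[int], length: int) -> list[float]:
    # Positions (1-based) of one group's residues -> the chain percentages at
    # which the first, 25%, 50%, 75% and 100% occurrences sit. The k-th
    # occurrence index for fraction f is ceil(f * n), floored at 1; an absent
    # group yields five zeros.
    if not positions:
        return [0.0] * 5
    n = len(positions)
    out = []
    for frac in (0.0, 0.25, 0.50, 0.75, 1.0):
        k = max(1, math.ceil(frac * n))
        out.append(100.0 * positions[k - 1] / length)
    return out


def encode_ctd(sequence: str) -> FeatureVector:
    """Composition/transition/distribution descriptors, 7 x 21 = 147 values.

    Per property scheme (three residue groups): C = percentage composition
    of each group (sums to 100); T = percentage, among the L-1 adjacent
    pairs, of transitions between each unordered group pair {1,2}, {1,3},
    {2,3}; D = for each group, the positions (as % of L) of its first, 25%,
    50%, 75% and 100% occurrences.
    """
    sequence = validate_sequence(sequence)
    length = len(sequence)
    schemes = load_ctd_schemes()
    names: list[str] = []
    values: list[float] = []
    for prop in CTD_PROPERTIES:
        mapping = schemes[prop]
        groups = [mapping[ch] for ch in sequence]
        # C
        for g in (1, 2, 3):
            names.append(f"CTD_{prop}_C_{g}")
            values.append(100.0 * groups.count(g) / length)
        # T
        pair_counts = {(1, 2): 0, (1, 3): 0, (2, 3): 0}
        for a, b in zip(groups, groups[1:]):
            if a != b:
                pair_counts[(min(a, b), max(a, b))] += 1
        for (a, b), cnt in pair_counts.items():
            names.append(f"CTD_{prop}_T_{a}{b}")
            values.append(100.0 * cnt / (length - 1))
        # D
        for g in (1, 2, 3):
            positions = [i + 1 for i, gg in enumerate(groups) if gg == g]
            dist = _ctd_distribution(positions, length)
            for pct, v in zip(("000", "025", "050", "075", "100"), dist):
                names.append(f"CTD_{prop}_D_{g}_{pct}")
                values.append(v)
    return FeatureVector(names, np.array(values))


_PCP_HYDROPHOBIC = frozenset("FIWLVMYCA")
_PCP_HYDROPHILIC = frozenset("RKNDEP")
_PCP_NEUTRAL = frozenset("THGSQ")
_PCP_POSITIVE = frozenset("KHR")
_PCP_NEGATIVE = frozenset("DE")
_PCP_TURN = frozenset("NGPS")

PCP_NAMES = [
    "PCP_hydrophobic_fraction",
    "PCP_hydrophilic_fraction",
    "PCP_neutral_fraction",
    "PCP_positive_fraction",
    "PCP_negative_fraction",
    "PCP_turn_fraction",
    "PCP_abs_charge_per_residue",
    "PCP_mol_weight_per_residue",
    "PCP_aliphatic_index",
]


def encode_pcp(sequence: str) -> FeatureVector:
    """Nine global physicochemical properties.

    Fractions of hydrophobic {F,I,W,L,V,M,Y,C,A}, hydrophilic {R,K,N,D,E,P},
    neutral {T,H,G,S,Q}, positively charged {K,H,R}, negatively charged
    {D,E} and turn-forming {N,G,P,S} residues; absolute net charge per
    residue |K+R-D-E|/n (histidine excluded from the arithmetic); average
    molecular weight per residue (residue masses plus one water, / n); and
    the aliphatic index (A + 2.9 V + 3.9 I + 3.9 L)/n on residue counts.
    """
    sequence = validate_sequence(sequence)
    n = len(sequence)
    cnt = {aa: sequence.count(aa) for aa in AMINO_ACIDS}
    masses = load_residue_masses()

    def frac(group) -> float:
        return sum(cnt[aa] for aa in group) / n

    mol_weight = (sum(masses[ch] for ch in sequence) + 18.015) / n
    aliphatic = (cnt["A"] + 2.9 * cnt["V"] + 3.9 * cnt["I"] + 3.9 * cnt["L"]) / n
    abs_charge = abs(cnt["K"] + cnt["R"] - cnt["D"] - cnt["E"]) / n
    values = [
        frac(_PCP_HYDROPHOBIC),
        frac(_PCP_HYDROPHILIC),
        frac(_PCP_NEUTRAL),
        frac(_PCP_POSITIVE),
        frac(_PCP_NEGATIVE),
        frac(_PCP_TURN),
        abs_charge,
        mol_weight,
        aliphatic,
    ]
    return FeatureVector(list(PCP_NAMES), np.array(values))


_SINGLE_ENCODERS = {
    "aac": encode_aac,
    "aai": encode_aai,
    "dpc": encode_dpc,
    "ctd": encode_ctd,
    "pcp": encode_pcp,
}


def encode_hybrid(sequence: str, parts=HYBRID_ORDER) -> FeatureVector:
    """Concatenation of encoders in the fixed order AAC, AAI, DPC, CTD, PCP."""
    parts = tuple(p.lower() for p in parts)
    if not parts:
        raise ParameterError("hybrid encoding requires a non-empty set of parts")
    unknown = set(parts) - set(HYBRID_ORDER)
    if unknown:
        raise ParameterError(f"unknown hybrid parts: {sorted(unknown)}")
    names: list[str] = []
    chunks: list[np.ndarray] = []
    for part in HYBRID_ORDER:
        if part in parts:
            fv = _SINGLE_ENCODERS[part](sequence)
            names.extend(fv.names)
            chunks.append(fv.values)
    return FeatureVector(names, np.concatenate(chunks))


def get_encoder(spec: str):
    """Resolve an encoder spec name to a sequence -> FeatureVector callable.

    Accepts the five single encoders plus ``"hybrid"`` (all five) and
    ``"hybrid:aac+dpc"``-style subsets.
    """
    spec = spec.lower()
    if spec in _SINGLE_ENCODERS:
        return _SINGLE_ENCODERS[spec]
    if spec == "hybrid":
        return encode_hybrid
    if spec.startswith("hybrid:"):
        parts = tuple(spec.split(":", 1)[1].split("+"))
        return lambda seq: encode_hybrid(seq, parts)
    raise ParameterError(
        f"unknown encoder {spec!r}; choose from "
        f"{sorted(_SINGLE_ENCODERS)} or 'hybrid[:a+b]'"
    )


def encode_dataset(dataset: PeptideDataset, encoder: str = "dpc") -> FeatureMatrix:
    """Encode every record of a dataset; rows follow dataset order."""
    enc = get_encoder(encoder)
    rows: list[np.ndarray] = []
    names: list[str] | None = None
    for rec in dataset:
        try:
            fv = enc(rec.sequence)
        except (SequenceError, ParameterError) as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
        if names is None:
            names = fv.names
        rows.append(fv.values)
    assert names is not None
    return FeatureMatrix(dataset.ids, names, np.vstack(rows))
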