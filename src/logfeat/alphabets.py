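"""Reduced-alphabet sequence encoding and k-mer (trimer) profiles.

Protein sequences are recoded into five physicochemical group letters
(positive/polar ``P``, negative/polar ``N``, hydrophobic ``H``, ring
``R``, special ``S``); DNA and ambiguous IUPAC DNA into four group
letters (``G``, strong/G-containing ambiguity ``Z``, the remaining
bases and ambiguity codes ``X``, and ``N``).  Sliding-window trimer
frequencies over the reduced alphabet give fixed-length profiles
(125-dimensional for protein, 64 for DNA) used as motif descriptors
for DNA-binding domains and for conserved ligand-binding motifs.

Nucleotide-containing ligands are grouped by moiety composition
(ribose, base, phosphate, flavin, nicotinamide, sulfur, thiamine,
other) into 11 group codes; the default 24-ligand assignment ships as
an editable YAML config.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "AlphabetSpec",
    "ReducedSequence",
    "TrimerVector",
    "PROTEIN_ALPHABET",
    "DNA_ALPHABET",
    "encode_protein",
    "encode_dna",
    "trimer_frequencies",
    "motif_profile",
    "load_ligand_groups",
    "ligand_group",
    "LIGAND_GROUP_CODES",
    "TrimerFrequencyEncoder",
]


@dataclass(frozen=True)
class AlphabetSpec:
    """A total residue-letter -> group-letter substitution table.

    Parameters
    ----------
    name:
        Identifier for the alphabet (``"protein"``, ``"dna"``, or a
        custom name).
    mapping:
        Residue letter to group letter, total over the declared input
        alphabet.  Input is matched case-insensitively.
    group_order:
        Ordered group letters; fixes the densified trimer layout
        (lexicographic product over this order).
    """

    name: str
    mapping: Mapping[str, str]
    group_order: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = set(self.mapping.values())
        if set(self.group_order) != groups:
            raise ValueError(
                f"group_order {self.group_order} does not match mapping "
                f"groups {sorted(groups)}"
            )
        if len(set(self.group_order)) != len(self.group_order):
            raise ValueError("group_order contains duplicates")
        for g in self.group_order:
            if not (len(g) == 1 and g.isupper()):
                raise ValueError(f"group letters must be single uppercase: {g!r}")

    @property
    def n_groups(self) -> int:
        return len(self.group_order)

    def trimer_order(self) -> list[str]:
        """All |groups|^3 trimers, lexicographic over ``group_order``."""
        return ["".join(t) for t in itertools.product(self.group_order, repeat=3)]

    @classmethod
    def from_yaml(cls, path) -> "AlphabetSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        mapping = {str(k).upper(): str(v).upper() for k, v in doc["mapping"].items()}
        order = tuple(str(g).upper() for g in doc["group_order"])
        return cls(name=str(doc.get("name", "custom")), mapping=mapping, group_order=order)


@dataclass(frozen=True)
class ReducedSequence:
    """A sequence recoded letter-for-letter into group letters."""

    source_id: str
    letters: str
    alphabet: str = "protein"

    def __len__(self) -> int:
        return len(self.letters)


@dataclass
class TrimerVector:
    """Sliding-window trimer counts over a reduced sequence."""

    counts: Counter = field(default_factory=Counter)
    total: int = 0
    normalized: bool = False

    def to_dense(self, spec: AlphabetSpec) -> np.ndarray:
        """Densify to the |groups|^3 layout fixed by ``spec``."""
        order = spec.trimer_order()
        return np.asarray([self.counts.get(t, 0.0) for t in order], dtype=float)


# Amino-acid groups by side-chain polarity and charge:
#   P positive or polar uncharged, N negative or polar uncharged,
#   H hydrophobic, R ring structures, S special properties.
_PROTEIN_GROUPS = {
    "P": "RKST",
    "N": "DENQ",
    "H": "AVILM",
    "R": "FWY",
    "S": "CGPH",
}

PROTEIN_ALPHABET = AlphabetSpec(
    name="protein",
    mapping={aa: g for g, members in _PROTEIN_GROUPS.items() for aa in members},
    group_order=("P", "N", "H", "R", "S"),
)

# IUPAC DNA incl. ambiguity codes collapsed to 4 groups.
_DNA_GROUPS = {
    "G": "G",
    "Z": "RSKBDV",
    "X": "ACTYWMH",
    "N": "N",
}

DNA_ALPHABET = AlphabetSpec(
    name="dna",
    mapping={b: g for g, members in _DNA_GROUPS.items() for b in members},
    group_order=("G", "Z", "X", "N"),
)


def _encode(seq: str, spec: AlphabetSpec, source_id: str) -> ReducedSequence:
    mapping = spec.mapping
    out = []
    for i, ch in enumerate(seq):
        try:
            out.append(mapping[ch.upper()])
        except KeyError:
            raise ValueError(
                f"unknown residue {ch!r} at position {i + 1} "
                f"for alphabet {spec.name!r}"
            ) from None
    return ReducedSequence(source_id=source_id, letters="".join(out), alphabet=spec.name)


def encode_protein(
    seq: str, spec: AlphabetSpec = PROTEIN_ALPHABET, source_id: str = ""
) -> ReducedSequence:
    """Recode an amino-acid sequence into group letters.

    Case-insensitive; non-canonical residues (U, B, Z, X, ...) are
    rejected by the default alphabet with a positional error — supply
    a custom :class:`AlphabetSpec` to map them.
    """
    return _encode(seq, spec, source_id)


def encode_dna(
    seq: str, spec: AlphabetSpec = DNA_ALPHABET, source_id: str = ""
) -> ReducedSequence:
    """Recode a (possibly ambiguous) IUPAC DNA string into group letters."""
    return _encode(seq, spec, source_id)


def trimer_frequencies(
    rs: ReducedSequence | str,
    spec: AlphabetSpec | None = None,
    normalize: bool = False,
) -> TrimerVector:
    """Count all length-3 windows (step 1) of a reduced sequence.

    ``total`` equals ``max(0, L - 2)``; with ``normalize=True`` counts
    are divided by ``total`` when it is positive.
    """
    letters = rs.letters if isinstance(rs, ReducedSequence) else rs
    counts: Counter = Counter(letters[i : i + 3] for i in range(len(letters) - 2))
    total = max(0, len(letters) - 2)
    vec = TrimerVector(counts=counts, total=total)
    if normalize and total > 0:
        vec.counts = Counter({k: v / total for k, v in counts.items()})
        vec.normalized = True
    return vec


def motif_profile(
    sequences: Iterable[str],
    spec: AlphabetSpec = PROTEIN_ALPHABET,
    agg: str = "mean",
) -> np.ndarray:
    """Aggregate profile of a conserved-motif family.

    Each member sequence is reduced, its trimer vector normalized, and
    the per-member vectors aggregated (``mean`` by default, ``sum``
    available).  Used for ligand-binding motif profiles.
    """
    rows = []
    for i, seq in enumerate(sequences):
        rs = _encode(seq, spec, source_id=f"member_{i}")
        rows.append(trimer_frequencies(rs, spec, normalize=True).to_dense(spec))
    if not rows:
        return np.zeros(spec.n_groups**3)
    mat = np.vstack(rows)
    if agg == "mean":
        return mat.mean(axis=0)
    if agg == "sum":
        return mat.sum(axis=0)
    raise ValueError(f"unknown aggregation {agg!r}")


LIGAND_GROUP_CODES = (
    "RBP", "RBPF", "RBPN", "RBPS", "RBPSO", "RBSO",
    "TOP", "OP", "TP", "RPF", "RPFO",
)


def load_ligand_groups(path=None) -> dict[str, str]:
    """Load the ligand -> moiety-group-code map (default: packaged YAML)."""
    if path is None:
        ref = resources.files("logfeat.data").joinpath("ligand_groups.yaml")
        doc = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    table = {str(k): str(v) for k, v in doc["ligands"].items()}
    bad = sorted(set(table.values()) - set(LIGAND_GROUP_CODES))
    if bad:
        raise ValueError(f"unknown ligand group codes in config: {bad}")
    return table


def ligand_group(ligand: str, group_map: Mapping[str, str] | None = None) -> str:
    """Return the moiety-composition group code of a ligand name."""
    if group_map is None:
        group_map = load_ligand_groups()
    try:
        return group_map[ligand]
    except KeyError:
        known = ", ".join(sorted(group_map))
        raise KeyError(f"unmapped ligand {ligand!r}; known ligands: {known}") from None


class TrimerFrequencyEncoder(BaseEstimator, TransformerMixin):
    """Transform raw sequences into dense reduced-alphabet trimer profiles.

    A stateless sklearn transformer: ``fit`` only validates parameters,
    ``transform`` maps an iterable of sequence strings to an
    ``(n_sequences, n_groups**3)`` float array.

    Parameters
    ----------
    alphabet:
        ``"protein"``, ``"dna"`` or an :class:`AlphabetSpec`.
    normalize:
        Divide each profile by its window count.
    """

    def __init__(self, alphabet="protein", normalize: bool = True):
        self.alphabet = alphabet
        self.normalize = normalize

    def _spec(self) -> AlphabetSpec:
        if isinstance(self.alphabet, AlphabetSpec):
            return self.alphabet
        if self.alphabet == "protein":
            return PROTEIN_ALPHABET
        if self.alphabet == "dna":
            return DNA_ALPHABET
        raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def fit(self, X: Sequence[str], y=None) -> "TrimerFrequencyEncoder":
        spec = self._spec()
        self.spec_ = spec
        self.n_features_out_ = spec.n_groups**3
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        check_is_fitted(self, "spec_")
        spec = self.spec_
        rows = [
            trimer_frequencies(
                _encode(seq, spec, source_id=str(i)), spec, normalize=self.normalize
            ).to_dense(spec)
            for i, seq in enumerate(X)
        ]
        if not rows:
            return np.zeros((0, self.n_features_out_))
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "spec_")
        return np.asarray(self.spec_.trimer_order(), dtype=object)
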