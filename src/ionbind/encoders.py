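"""Fragment feature encoders: component, conservation, entropy, propensity.

Four encodings are computed per fragment and concatenated in fixed order:

component
    Relative frequency of every category (vacancy included) of each
    annotation track within the fragment: 21+4+5+3+4+3 = 40 values for the
    full track set, 37 when disorder is excluded (basic set).

conservation (position weight matrices)
    Per track, two L x q matrices are fitted on the positive and negative
    training fragments respectively, with elements
    ``m[i, j] = ln(p[i, j] / p0[j])`` where
    ``p[i, j] = (n[i, j] + sqrt(N_i)/q) / (N_i + sqrt(N_i))`` and ``p0`` is
    the pooled background category frequency.  A fragment scores m at its
    observed category per position: 2L values per track, 6 tracks (full) or
    5 (basic).

entropy
    Shannon entropy (bits) of the fragment's charge (q=4) and hydropathy
    (q=7) category distributions, vacancy included: 2 values.

propensity (Chou-Fasman-style factors)
    ``F[i, j] = (n_ij / N_i) / (N_j / N_t)``: over/under-representation of
    the central residue's category i among class-j centres relative to the
    class share.  The pair (F_binding, F_non-binding) is emitted for the
    central residue's amino acid, charge and hydropathy: 6 values.

All encoders are fitted exclusively on training fragments; fitted objects
record the identities of their training fragments so that cross-validation
can assert the absence of leakage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .discretizers import CONSERVATION_TRACKS, SCHEMES, TRACKS
from .windows import Fragment

#: (feature name, column in the track tensor, number of real categories)
PROPENSITY_FEATURES = (("amino_acid", 0, 20), ("charge", 6, 3), ("hydropathy", 7, 6))

#: entropy uses the charge / hydropathy tracks with vacancy as a category
ENTROPY_TRACKS = (("charge", 6, 4), ("hydropathy", 7, 7))

_TRACK_COL = {name: i for i, name in enumerate(TRACKS)}


class LeakageError(RuntimeError):
    """An encoder fitted on one partition was applied where it must not be."""


class NotFittedEncoderError(RuntimeError):
    pass


def stack_fragments(fragments: Sequence[Fragment]):
    """Stack fragments into a (n, L, 8) state tensor plus labels and ids."""
    if len(fragments) == 0:
        raise ValueError("no fragments given")
    L = fragments[0].window_length
    states = np.stack([f.states for f in fragments])
    labels = np.fromiter((f.label for f in fragments), dtype=np.int8, count=len(fragments))
    ids = frozenset((f.chain_id, f.center_index) for f in fragments)
    if states.shape[1] != L:
        raise ValueError("fragments have inconsistent window lengths")
    return states, labels, ids


# ---------------------------------------------------------------------------
# propensity factors


@dataclass
class PropensityTable:
    """F_ij factors for one feature, with the raw counts kept for audit."""

    feature_name: str
    categories: tuple[str, ...]  # real categories only; centres are never vacancy
    n_ij: np.ndarray  # (q, 2); column 0 = binding, 1 = non-binding
    F: np.ndarray = field(init=False)  # (q, 2)
    N_i: np.ndarray = field(init=False)  # (q,)
    N_j: np.ndarray = field(init=False)  # (2,)
    N_t: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_ij = np.asarray(self.n_ij, dtype=float)
        self.N_i = self.n_ij.sum(axis=1)
        self.N_j = self.n_ij.sum(axis=0)
        self.N_t = int(self.N_j.sum())
        if (self.N_j == 0).any():
            raise ValueError(
                f"propensity table {self.feature_name}: training data must "
                "contain both binding and non-binding central residues"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            p_ij = self.n_ij / self.N_i[:, None]
            self.F = p_ij / (self.N_j / self.N_t)[None, :]
        absent = self.N_i == 0
        if absent.any():
            warnings.warn(
                f"propensity table {self.feature_name}: categories "
                f"{[self.categories[i] for i in np.nonzero(absent)[0]]} unseen "
                "in training data; neutral factor F=1 applied",
                stacklevel=2,
            )
            self.F[absent] = 1.0

    def lookup(self, category_index: int) -> np.ndarray:
        """(F_binding, F_non-binding) for a central-residue category."""
        return self.F[category_index]


def fit_propensity(fragments: Sequence[Fragment]) -> dict[str, PropensityTable]:
    """Fit the three propensity tables (amino acid, charge, hydropathy)."""
    states, labels, _ = stack_fragments(fragments)
    return fit_propensity_from_states(states, labels)


def fit_propensity_from_states(
    states: np.ndarray, labels: np.ndarray
) -> dict[str, PropensityTable]:
    half = (states.shape[1] - 1) // 2
    centers = states[:, half, :]
    tables: dict[str, PropensityTable] = {}
    for name, col, q in PROPENSITY_FEATURES:
        codes = centers[:, col]
        if (codes >= q).any():
            raise ValueError(f"{name}: vacancy at a fragment centre")
        n_ij = np.zeros((q, 2))
        for j, cls in enumerate((1, 0)):  # column 0 = binding
            n_ij[:, j] = np.bincount(codes[labels == cls], minlength=q)
        scheme = "aa" if name == "amino_acid" else name
        tables[name] = PropensityTable(
            feature_name=name,
            categories=SCHEMES[scheme].categories[:-1],
            n_ij=n_ij,
        )
    return tables


def encode_propensity(
    fragment: Fragment, tables: Mapping[str, PropensityTable]
) -> np.ndarray:
    """6-dimensional propensity feature of the fragment's central residue."""
    half = (fragment.window_length - 1) // 2
    out = np.empty(6)
    for k, (name, col, _q) in enumerate(PROPENSITY_FEATURES):
        out[2 * k : 2 * k + 2] = tables[name].lookup(int(fragment.states[half, col]))
    return out


# ---------------------------------------------------------------------------
# position weight matrices (site conservation)


@dataclass
class WeightMatrixPair:
    """Positive- and negative-set log-odds matrices for one annotation track."""

    track_name: str
    window_length: int
    q: int
    M_pos: np.ndarray  # (L, q)
    M_neg: np.ndarray  # (L, q)
    p0: np.ndarray  # (q,) background category frequencies
    pseudocount: str = "sqrt_N_over_q"
    background_floor: float = 0.0
    train_ids: frozenset = frozenset()


def _position_counts(track_states: np.ndarray, q: int) -> np.ndarray:
    """Category counts per window position: (L, q) from (n, L) codes."""
    n, L = track_states.shape
    flat = track_states + np.arange(L)[None, :] * q
    return np.bincount(flat.ravel(), minlength=L * q).reshape(L, q).astype(float)


def _pwm(counts: np.ndarray, p0: np.ndarray) -> np.ndarray:
    N = counts.sum(axis=1, keepdims=True)  # fragments per class, same at each position
    root = np.sqrt(N)
    q = counts.shape[1]
    p = (counts + root / q) / (N + root)
    return np.log(p / p0[None, :])


def fit_weight_matrices(
    fragments: Sequence[Fragment] | None,
    track: str,
    *,
    states: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    train_ids: frozenset = frozenset(),
) -> WeightMatrixPair:
    """Fit the positive/negative PWM pair for one track on training fragments.

    The background p0 is the pooled category frequency over all positions of
    the whole training partition (both classes), floored at 1/(10*q*total)
    so every log-odds element stays finite.
    """
    if states is None:
        states, labels, train_ids = stack_fragments(list(fragments))
    col = _TRACK_COL[track]
    q = SCHEMES[track].q
    track_states = states[:, :, col]
    labels = np.asarray(labels)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("need at least one positive and one negative fragment")

    total = track_states.size
    p0 = np.bincount(track_states.ravel(), minlength=q).astype(float) / total
    floor = 1.0 / (10.0 * q * total)
    unseen = p0 < floor
    if unseen.any():
        warnings.warn(
            f"track {track}: categories {np.nonzero(unseen)[0].tolist()} "
            "absent from training background; floor applied",
            stacklevel=2,
        )
    p0 = np.maximum(p0, floor)

    M_pos = _pwm(_position_counts(track_states[labels == 1], q), p0)
    M_neg = _pwm(_position_counts(track_states[labels == 0], q), p0)
    return WeightMatrixPair(
        track_name=track,
        window_length=states.shape[1],
        q=q,
        M_pos=M_pos,
        M_neg=M_neg,
        p0=p0,
        background_floor=floor,
        train_ids=train_ids,
    )


def encode_conservation(
    fragment: Fragment, matrix_pairs: Mapping[str, WeightMatrixPair]
) -> np.ndarray:
    """Per-position PWM scores: for each track, L values under M_pos then M_neg."""
    L = fragment.window_length
    blocks = []
    for track in CONSERVATION_TRACKS:
        if track not in matrix_pairs:
            continue
        pair = matrix_pairs[track]
        if pair.window_length != L:
            raise ValueError(
                f"track {track}: matrix window {pair.window_length} != fragment {L}"
            )
        codes = fragment.states[:, _TRACK_COL[track]]
        idx = np.arange(L)
        blocks.append(pair.M_pos[idx, codes])
        blocks.append(pair.M_neg[idx, codes])
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# entropy and component information


def _block_frequencies(track_states: np.ndarray, q: int) -> np.ndarray:
    """(n, q) within-fragment category frequencies from (n, L) codes."""
    n, L = track_states.shape
    flat = track_states + np.arange(n)[:, None] * q
    return np.bincount(flat.ravel(), minlength=n * q).reshape(n, q) / L


def _entropy_bits(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def encode_entropy(fragment: Fragment) -> np.ndarray:
    """Shannon entropies (bits) of the charge (q=4) and hydropathy (q=7) content."""
    out = np.empty(2)
    for k, (_name, col, q) in enumerate(ENTROPY_TRACKS):
        p = _block_frequencies(fragment.states[None, :, col], q)
        out[k] = _entropy_bits(p)[0]
    return out


def encode_component(fragment: Fragment, feature_set: str = "full") -> np.ndarray:
    """Within-fragment category frequencies per track (40 dims full, 37 basic)."""
    tracks = _component_tracks(feature_set)
    return np.concatenate(
        [
            _block_frequencies(fragment.states[None, :, _TRACK_COL[t]], SCHEMES[t].q)[0]
            for t in tracks
        ]
    )


def _component_tracks(feature_set: str) -> tuple[str, ...]:
    if feature_set == "full":
        return CONSERVATION_TRACKS
    if feature_set == "basic":
        return tuple(t for t in CONSERVATION_TRACKS if t != "disorder")
    raise ValueError(f"unknown feature set {feature_set!r}")


# ---------------------------------------------------------------------------
# the sklearn transformer tying it together


class FragmentFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer from fragments to the assembled numeric feature matrix.

    Parameters
    ----------
    feature_set : {"full", "basic"}
        "full" emits component(40) + conservation(6*2L) + entropy(2) +
        propensity(6).  "basic" excludes the disorder track and the
        propensity block everywhere: component(37) + conservation(5*2L) +
        entropy(2).

    Fitted attributes (trailing underscore) include the propensity tables,
    the per-track weight-matrix pairs, the training-fragment identity set
    used for leakage assertions and the output feature names.
    """

    def __init__(self, feature_set: str = "full"):
        self.feature_set = feature_set

    # -- sklearn API --------------------------------------------------------

    def fit(self, X: Sequence[Fragment], y=None) -> "FragmentFeaturizer":
        fragments = list(X)
        _component_tracks(self.feature_set)  # validate param
        states, labels, ids = stack_fragments(fragments)
        self.window_length_ = states.shape[1]
        self.train_ids_ = ids
        self.matrices_ = {
            t: fit_weight_matrices(None, t, states=states, labels=labels, train_ids=ids)
            for t in _component_tracks(self.feature_set)
        }
        if self.feature_set == "full":
            self.tables_ = fit_propensity_from_states(states, labels)
        else:
            self.tables_ = {}
        self.feature_names_ = self._feature_names()
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X: Sequence[Fragment]) -> np.ndarray:
        self._check_fitted()
        fragments = list(X)
        states, _labels, _ids = stack_fragments(fragments)
        if states.shape[1] != self.window_length_:
            raise ValueError(
                f"fragments have window length {states.shape[1]}, "
                f"featurizer was fitted with {self.window_length_}"
            )
        tracks = _component_tracks(self.feature_set)
        n, L = states.shape[0], self.window_length_
        blocks: list[np.ndarray] = []

        for t in tracks:  # component
            blocks.append(_block_frequencies(states[:, :, _TRACK_COL[t]], SCHEMES[t].q))

        idx = np.arange(L)
        for t in tracks:  # conservation
            pair = self.matrices_[t]
            codes = states[:, :, _TRACK_COL[t]]
            blocks.append(pair.M_pos[idx[None, :], codes])
            blocks.append(pair.M_neg[idx[None, :], codes])

        for _name, col, q in ENTROPY_TRACKS:  # entropy
            p = _block_frequencies(states[:, :, col], q)
            blocks.append(_entropy_bits(p)[:, None])

        if self.feature_set == "full":  # propensity
            half = (L - 1) // 2
            centers = states[:, half, :]
            for name, col, _q in PROPENSITY_FEATURES:
                blocks.append(self.tables_[name].F[centers[:, col]])

        return np.hstack(blocks)

    # -- leakage guard ------------------------------------------------------

    def assert_disjoint(self, fragments: Iterable[Fragment]) -> None:
        """Raise LeakageError if any fragment was part of the training set."""
        self._check_fitted()
        overlap = [
            (f.chain_id, f.center_index)
            for f in fragments
            if (f.chain_id, f.center_index) in self.train_ids_
        ]
        if overlap:
            raise LeakageError(
                f"{len(overlap)} evaluation fragment(s) were used to fit the "
                f"encoders (first: {overlap[0]})"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "feature_set": self.feature_set,
            "window_length": self.window_length_,
            "train_ids": sorted([list(t) for t in self.train_ids_]),
            "tables": {
                name: {
                    "feature_name": tab.feature_name,
                    "categories": list(tab.categories),
                    "n_ij": tab.n_ij.tolist(),
                }
                for name, tab in self.tables_.items()
            },
            "matrices": {
                t: {
                    "track_name": m.track_name,
                    "window_length": m.window_length,
                    "q": m.q,
                    "M_pos": m.M_pos.tolist(),
                    "M_neg": m.M_neg.tolist(),
                    "p0": m.p0.tolist(),
                    "pseudocount": m.pseudocount,
                    "background_floor": m.background_floor,
                }
                for t, m in self.matrices_.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FragmentFeaturizer":
        fz = cls(feature_set=d["feature_set"])
        fz.window_length_ = int(d["window_length"])
        fz.train_ids_ = frozenset((c, int(i)) for c, i in d["train_ids"])
        fz.tables_ = {
            name: PropensityTable(
                feature_name=td["feature_name"],
                categories=tuple(td["categories"]),
                n_ij=np.asarray(td["n_ij"]),
            )
            for name, td in d["tables"].items()
        }
        fz.matrices_ = {
            t: WeightMatrixPair(
                track_name=md["track_name"],
                window_length=int(md["window_length"]),
                q=int(md["q"]),
                M_pos=np.asarray(md["M_pos"]),
                M_neg=np.asarray(md["M_neg"]),
                p0=np.asarray(md["p0"]),
                pseudocount=md["pseudocount"],
                background_floor=float(md["background_floor"]),
                train_ids=fz.train_ids_,
            )
            for t, md in d["matrices"].items()
        }
        fz.feature_names_ = fz._feature_names()
        fz.n_features_out_ = len(fz.feature_names_)
        return fz

    # -- helpers ------------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "matrices_"):
            raise NotFittedEncoderError(
                "FragmentFeaturizer must be fitted before use"
            )

    def _feature_names(self) -> list[str]:
        tracks = _component_tracks(self.feature_set)
        L = self.window_length_
        names: list[str] = []
        for t in tracks:
            names += [f"component:{t}:{c}" for c in SCHEMES[t].categories]
        for t in tracks:
            names += [f"conservation:{t}:pos:{i + 1}" for i in range(L)]
            names += [f"conservation:{t}:neg:{i + 1}" for i in range(L)]
        names += ["entropy:charge", "entropy:hydropathy"]
        if self.feature_set == "full":
            for name, _col, _q in PROPENSITY_FEATURES:
                names += [f"propensity:{name}:binding", f"propensity:{name}:non_binding"]
        return names


def assemble_features(fragment: Fragment, featurizer: FragmentFeaturizer) -> np.ndarray:
    """Feature vector of a single fragment under a fitted featurizer."""
    return featurizer.transform([fragment])[0]


def feature_dimension(feature_set: str, window_length: int) -> int:
    """Assembled feature dimension: 48 + 12L (full), 39 + 10L (basic)."""
    if feature_set == "full":
        return 40 + 6 * 2 * window_length + 2 + 6
    if feature_set == "basic":
        return 37 + 5 * 2 * window_length + 2
    raise ValueError(f"unknown feature set {feature_set!r}")


def save_bundle(featurizer: FragmentFeaturizer, scaler, path) -> None:
    """Serialize a fitted featurizer plus optional standardizer to JSON."""
    d = {"featurizer": featurizer.to_dict()}
    if scaler is not None:
        d["scaler"] = {"mean": scaler.mean_.tolist(), "scale": scaler.scale_.tolist()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(d, fh)


def load_bundle(path):
    from sklearn.preprocessing import StandardScaler

    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    try:
        fz = FragmentFeaturizer.from_dict(d["featurizer"])
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed encoder bundle {path}: {exc}") from exc
    scaler = None
    if "scaler" in d:
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(d["scaler"]["mean"])
        scaler.scale_ = np.asarray(d["scaler"]["scale"])
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = scaler.mean_.shape[0]
        scaler.with_mean = True
        scaler.with_std = True
    return fz, scaler
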