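"""SVM feature construction from sequence profiles and topology.

Per-residue lipid-exposure features are a sliding window of profile
rows (window 7 by default, 7 x 20 = 140 values) centred on the target
residue, with zero blocks beyond the termini. Per-pair contact features
concatenate the two residue windows (280 values), the two raw lipid
SVM scores, a one-hot sequence-separation encoding (8 bins: <=50, 75,
100, 125, 150, 175, 200, >200) and the two relative in-helix positions
("relative Z"): z = within-helix position / helix length, with the
second residue's value flipped to 1 - (pos - start)/length when the
two helices have odd index difference (antiparallel in a membrane), so
that aligned heights get similar values. All features are Z-score
normalized with statistics fitted on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from helixpack.io_formats import (
    HelixSpan,
    ProteinRecord,
    SequenceProfile,
    Topology,
    ValidationError,
)


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-vector geometry for both classifiers."""

    window: int = 7
    separation_bins: tuple[int, ...] = (50, 75, 100, 125, 150, 175, 200)
    profile_width: int = 20
    thermometer_separation: bool = False  # cumulative instead of one-hot

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and positive, got {self.window}")
        if list(self.separation_bins) != sorted(set(self.separation_bins)):
            raise ValueError("separation bins must be strictly ascending")

    @property
    def lipid_feature_length(self) -> int:
        return self.window * self.profile_width

    @property
    def pair_profile_length(self) -> int:
        return 2 * self.window * self.profile_width

    @property
    def n_separation_bins(self) -> int:
        return len(self.separation_bins) + 1

    @property
    def pair_feature_length(self) -> int:
        # profile windows + 2 lipid scores + separation bins + 2 z values
        return self.pair_profile_length + 2 + self.n_separation_bins + 2


@dataclass(frozen=True)
class NormalizationStats:
    """Column means and standard deviations of a training matrix."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[-1] != self.mean.shape[0]:
            raise ValidationError(
                f"feature width {matrix.shape[-1]} does not match "
                f"normalization width {self.mean.shape[0]}"
            )
        sd = np.where(self.sd > 0, self.sd, 1.0)
        out = (matrix - self.mean) / sd
        # constant training columns carry no information -> exactly 0
        out[..., self.sd == 0] = 0.0
        return out


def fit_zscore(train_matrix: np.ndarray) -> NormalizationStats:
    """Fit per-column Z-score statistics (population sd) on training data."""
    train_matrix = np.asarray(train_matrix, dtype=float)
    if train_matrix.size == 0:
        raise ValidationError("cannot fit normalization on an empty matrix")
    return NormalizationStats(
        mean=train_matrix.mean(axis=0), sd=train_matrix.std(axis=0)
    )


def fit_apply_zscore(
    train_matrix: np.ndarray, *other_matrices: np.ndarray
) -> tuple:
    """Z-score the training matrix and transform any held-out matrices
    with the same statistics. Returns the transformed matrices followed
    by the :class:`NormalizationStats`."""
    stats = fit_zscore(train_matrix)
    out = [stats.transform(train_matrix)]
    out.extend(stats.transform(m) for m in other_matrices)
    out.append(stats)
    return tuple(out)


def profile_window(
    profile: SequenceProfile, center: int, window: int = 7
) -> np.ndarray:
    """Concatenated profile rows ``center - w//2 .. center + w//2``
    (1-based center); positions beyond the termini contribute zeros."""
    if not 1 <= center <= profile.length:
        raise ValidationError(
            f"window center {center} outside sequence of length {profile.length}"
        )
    half = window // 2
    width = profile.scores.shape[1]
    out = np.zeros(window * width)
    for k, pos in enumerate(range(center - half, center + half + 1)):
        if 1 <= pos <= profile.length:
            out[k * width : (k + 1) * width] = profile.scores[pos - 1]
    return out


def separation_encoding(
    d: int, config: FeatureConfig | None = None
) -> np.ndarray:
    """Encode sequence separation ``d = |i - j|`` into bins.

    One-hot by default: bit k for the smallest bin boundary >= d
    (inclusive-left: d <= 50 -> bin 1, 50 < d <= 75 -> bin 2, ...),
    last bit for d > 200. A thermometer (cumulative) variant is
    available via the config flag.
    """
    config = config or FeatureConfig()
    if d < 1:
        raise ValidationError(f"sequence separation must be >= 1, got {d}")
    bins = config.separation_bins
    out = np.zeros(len(bins) + 1)
    slot = len(bins)  # overflow bin
    for k, edge in enumerate(bins):
        if d <= edge:
            slot = k
            break
    if config.thermometer_separation:
        out[slot:] = 1.0
    else:
        out[slot] = 1.0
    return out


def relative_position(pos: int, helix: HelixSpan, flip: bool = False) -> float:
    """Relative in-helix position ("relative Z") in (0, 1].

    z = (pos - start + 1) / length; when ``flip`` is set the value is
    taken from the other end: 1 - (pos - start)/length, so flipping is
    an involution and stays in (0, 1].
    """
    if pos not in helix:
        raise ValidationError(
            f"residue {pos} outside helix {helix.index} ({helix.start}-{helix.end})"
        )
    length = len(helix)
    if flip:
        return 1.0 - (pos - helix.start) / length
    return (pos - helix.start + 1) / length


def relative_position_pair(
    pos_i: int, helix_i: HelixSpan, pos_j: int, helix_j: HelixSpan
) -> tuple[float, float]:
    """Relative-Z pair for a residue pair on two different helices.

    The second residue's value is flipped when the helix index
    difference is odd (sequence-adjacent helices run antiparallel
    through the membrane, so matching heights lie at opposite span
    ends)."""
    flip = (helix_j.index - helix_i.index) % 2 == 1
    return (
        relative_position(pos_i, helix_i),
        relative_position(pos_j, helix_j, flip=flip),
    )


def build_lipid_features(
    record: ProteinRecord,
    profile: SequenceProfile,
    topology: Topology,
    config: FeatureConfig | None = None,
) -> tuple[np.ndarray, list[int]]:
    """One window row per TM residue. Returns (matrix, residue indices)."""
    config = config or FeatureConfig()
    if profile.length != record.length:
        raise ValidationError(
            f"profile length {profile.length} != sequence length {record.length}"
        )
    residues = topology.tm_residues()
    if not residues:
        raise ValidationError("topology contains no TM helices")
    matrix = np.stack(
        [profile_window(profile, pos, config.window) for pos in residues]
    )
    return matrix, residues


def enumerate_pairs(topology: Topology) -> list[tuple[int, int]]:
    """All inter-helix residue pairs (i, j), i < j, in deterministic order."""
    out = []
    helices = topology.helices
    for ha in helices:
        for hb in helices:
            if hb.index <= ha.index:
                continue
            for i in range(ha.start, ha.end + 1):
                for j in range(hb.start, hb.end + 1):
                    out.append((i, j))
    return out


def build_pair_features(
    record: ProteinRecord,
    profile: SequenceProfile,
    topology: Topology,
    lipid_scores: dict[int, float],
    config: FeatureConfig | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Contact-classifier features for every inter-helix residue pair.

    Row layout: [window(i) | window(j) | lipid(i), lipid(j) |
    separation one-hot | z_i, z_j]. Returns (matrix, pair list).
    """
    config = config or FeatureConfig()
    if profile.length != record.length:
        raise ValidationError(
            f"profile length {profile.length} != sequence length {record.length}"
        )
    pairs = enumerate_pairs(topology)
    if not pairs:
        raise ValidationError("topology has fewer than two TM helices")
    span_of = {h.index: h for h in topology.helices}
    windows = {
        pos: profile_window(profile, pos, config.window)
        for pos in topology.tm_residues()
    }
    rows = np.empty((len(pairs), config.pair_feature_length))
    for r, (i, j) in enumerate(pairs):
        hi = span_of[topology.helix_of(i)]
        hj = span_of[topology.helix_of(j)]
        if i not in lipid_scores or j not in lipid_scores:
            raise ValidationError(f"missing lipid score for pair ({i}, {j})")
        zi, zj = relative_position_pair(i, hi, j, hj)
        rows[r] = np.concatenate(
            [
                windows[i],
                windows[j],
                [lipid_scores[i], lipid_scores[j]],
                separation_encoding(j - i, config),
                [zi, zj],
            ]
        )
    return rows, pairs
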