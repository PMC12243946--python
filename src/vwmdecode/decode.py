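"""Within- and cross-decoding of object identity from beta patterns.

Two families of analyses, both pairwise linear-SVM decoding on z-normalized
period-averaged beta patterns with a leave-one-split-out rotation (train on
3 splits = 21 patterns per condition, test on the held-out split = 7):

1. Distractor -> target cross-decoding.  A classifier trained to tell a pair
   of objects apart when they were delay-period *distractors* is tested on
   the same pair when they were memory *targets* (delay or encoding period,
   with- or without-distractor trials).  Run in one direction only: distractor
   decoding sits at ceiling, so the reverse direction would not track signal.

2. Encoding <-> delay cross-decoding for targets, averaged over both training
   directions (neither period is at ceiling).

A cross-decoding drop relative to the matched within-decoding indexes a
representational transformation; the two are combined into the
cross-decoding ratio (cross - 0.5) / (within - 0.5), which is 1 under full
generalization and 0 under none, and is insensitive to overall SNR.

Four-way decoding is rejected by construction: targets never share a trial
with a same-category distractor, so distractor identity is confounded with
target identity in any four-way scheme.  Pairwise decoding with the
irrelevant object held fixed avoids the confound.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .design import ObjectID, TrialCondition
from .glm import BetaPatternSet, PeriodPatternSet, average_period

CHANCE = 0.5

#: ROI sector membership (posterior = early visual, ventral = object-selective
#: occipitotemporal, dorsal = posterior parietal)
SECTORS: dict[str, tuple[str, ...]] = {
    "posterior": ("V1", "V2", "V3", "V4"),
    "ventral": ("LOT", "VOT"),
    "dorsal": ("IPS2", "IPS3", "IPS4"),
}


def sector_of(roi: str) -> str | None:
    for sector, rois in SECTORS.items():
        if roi in rois:
            return sector
    return None


# ---------------------------------------------------------------------------
# scheme definitions


@dataclass(frozen=True)
class DecodingScheme:
    """Train/test sources for one decoding analysis.

    ``role`` is which trial element carries the decoded identity (``target``
    or ``distractor``); ``period`` selects the averaged window; ``trial_set``
    selects with- vs without-distractor trials for the *target* side
    (distractor patterns exist only in with-distractor trials).
    """

    name: str
    train_role: str
    train_period: str
    test_role: str
    test_period: str
    train_trial_set: str = "with_distractors"
    test_trial_set: str = "with_distractors"
    irrelevant_match: str = "same"
    bidirectional: bool = False

    def __post_init__(self):
        if self.train_role == "distractor" and self.train_trial_set != "with_distractors":
            raise ValueError("distractor patterns only exist in with-distractor trials")
        if self.test_role == "distractor" and self.train_role == "target":
            raise ValueError(
                "training on targets to decode distractors is disabled: "
                "distractor decoding is at ceiling, so accuracies would not "
                "track the underlying signal; cross-decoding runs in one "
                "direction only (train on distractors, decode targets)"
            )

    @property
    def is_cross(self) -> bool:
        return (self.train_role, self.train_period, self.train_trial_set) != (
            self.test_role,
            self.test_period,
            self.test_trial_set,
        )


_SCHEMES = {
    "within_target_delay": dict(
        train_role="target", train_period="delay", test_role="target", test_period="delay"
    ),
    "cross_distractor_to_target_delay": dict(
        train_role="distractor", train_period="delay", test_role="target", test_period="delay"
    ),
    "within_target_encoding": dict(
        train_role="target", train_period="encoding",
        test_role="target", test_period="encoding",
    ),
    "within_distractor_delay": dict(
        train_role="distractor", train_period="delay",
        test_role="distractor", test_period="delay",
    ),
    "cross_distractor_to_target_encoding": dict(
        train_role="distractor", train_period="delay",
        test_role="target", test_period="encoding",
    ),
    "cross_to_no_distractor_targets": dict(
        train_role="distractor", train_period="delay",
        test_role="target", test_period="delay", test_trial_set="without_distractors",
    ),
    "within_encoding": dict(
        train_role="target", train_period="encoding",
        test_role="target", test_period="encoding",
    ),
    "within_delay": dict(
        train_role="target", train_period="delay", test_role="target", test_period="delay"
    ),
    "cross_encoding_delay": dict(
        train_role="target", train_period="encoding",
        test_role="target", test_period="delay", bidirectional=True,
    ),
}


def get_scheme(
    name: str, trial_set: str = "with_distractors", irrelevant_match: str = "same"
) -> DecodingScheme:
    """Look up a named scheme; ``trial_set`` applies to the target side of
    the generic within/cross encoding-delay schemes."""
    if name not in _SCHEMES:
        raise KeyError(f"unknown scheme {name!r}; known: {sorted(_SCHEMES)}")
    kw = dict(_SCHEMES[name])
    if name in ("within_encoding", "within_delay", "cross_encoding_delay"):
        kw["train_trial_set"] = trial_set
        kw["test_trial_set"] = trial_set
    return DecodingScheme(name=name, irrelevant_match=irrelevant_match, **kw)


@dataclass(frozen=True)
class PairInstance:
    """One decoded object pair with its irrelevant-object assignment."""

    pair: tuple[ObjectID, ObjectID]
    irrelevant_train: ObjectID | None
    irrelevant_test: ObjectID | None

    def __post_init__(self):
        for irr in (self.irrelevant_train, self.irrelevant_test):
            if irr is not None and irr in self.pair:
                raise ValueError("irrelevant object must not belong to the decoded pair")


def _needs_irrelevant(role: str, trial_set: str) -> bool:
    return role == "distractor" or trial_set == "with_distractors"


def enumerate_pair_instances(scheme: DecodingScheme) -> list[PairInstance]:
    """All decoded pairs crossed with eligible irrelevant objects.

    6 unordered pairs; with an irrelevant object on both sides and
    ``irrelevant_match='same'`` each pair contributes one instance per
    eligible irrelevant (2), i.e. 12 instances; 'different' pairs the two
    eligible irrelevants in both orders (also 12); a side without an
    irrelevant object (no-distractor trials) contributes none there.
    """
    objs = list(ObjectID)
    train_irr = _needs_irrelevant(scheme.train_role, scheme.train_trial_set)
    test_irr = _needs_irrelevant(scheme.test_role, scheme.test_trial_set)
    out: list[PairInstance] = []
    for pair in itertools.combinations(objs, 2):
        others = [o for o in objs if o not in pair]
        if train_irr and test_irr:
            if scheme.irrelevant_match == "same":
                combos = [(c, c) for c in others]
            else:
                combos = [(c, d) for c in others for d in others if c != d]
        elif train_irr:
            combos = [(c, None) for c in others]
        elif test_irr:
            combos = [(None, c) for c in others]
        else:
            combos = [(None, None)]
        for c_train, c_test in combos:
            out.append(PairInstance(pair, c_train, c_test))
    return out


def _condition_for(role: str, obj: ObjectID, irrelevant: ObjectID | None) -> TrialCondition:
    if role == "target":
        return TrialCondition(obj, irrelevant)
    if role == "distractor":
        if irrelevant is None:
            raise ValueError("distractor patterns require a target (irrelevant) object")
        return TrialCondition(irrelevant, obj)
    raise ValueError(f"unknown role {role!r}")


# ---------------------------------------------------------------------------
# normalization and the classifier


def znorm(pattern: np.ndarray) -> np.ndarray:
    """z-normalize one response pattern across its vertices (population SD),
    removing amplitude differences between conditions/periods/ROIs."""
    x = np.asarray(pattern, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("pattern must be a 1-D vector of >= 2 vertices")
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance pattern cannot be z-normalized")
    return (x - x.mean()) / sd


def decode_once(
    train_patterns: np.ndarray,
    train_labels: np.ndarray,
    test_patterns: np.ndarray,
    test_labels: np.ndarray,
) -> float:
    """Fit a linear maximum-margin classifier (C=1) and return test accuracy.

    Boundary ties resolve to the first class in sorted label order.
    """
    from sklearn.svm import SVC

    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    classes = np.unique(train_labels)
    if classes.size != 2:
        if classes.size > 2:
            raise ValueError(
                "only pairwise decoding is supported: with four object "
                "categories, distractor identity is unbalanced across target "
                "categories (a target never shares a trial with a same-"
                "category distractor), so multiway decoding would read out "
                "the strong distractor signal instead of the target; decode "
                "pairs with the irrelevant object held fixed"
            )
        raise ValueError("training set must contain exactly two classes")
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(train_patterns, train_labels)
    d = clf.decision_function(test_patterns)
    pred = np.where(d > 0, clf.classes_[1], clf.classes_[0])
    return float(np.mean(pred == test_labels))


# ---------------------------------------------------------------------------
# rotation over splits


def _gather(
    periods: dict[str, PeriodPatternSet],
    scheme_side: tuple[str, str, str],
    instance_irr: ObjectID | None,
    pair: tuple[ObjectID, ObjectID],
    splits: list[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack z-normalized patterns and labels for one side of the decoder."""
    role, period, _trial_set = scheme_side
    pset = periods[period]
    cond_index = {c: i for i, c in enumerate(pset.conditions)}
    X, y = [], []
    for label, obj in enumerate(pair):
        cond = _condition_for(role, obj, instance_irr)
        ci = cond_index[cond]
        for s in splits:
            keys = pset.split_keys(s)
            if not keys:
                raise ValueError(f"split {s} has no patterns")
            for key in keys:
                X.append(znorm(pset.patterns[key][ci]))
                y.append(label)
    return np.array(X), np.array(y)


def rotate_and_average(
    periods: dict[str, PeriodPatternSet],
    scheme: DecodingScheme,
    instance: PairInstance,
) -> float:
    """Leave-one-split-out accuracy, averaged over the 4 rotations (and over
    both training directions for bidirectional schemes)."""
    n_splits = periods[scheme.train_period].n_splits
    if n_splits < 2:
        raise ValueError("rotation requires at least 2 splits")
    train_side = (scheme.train_role, scheme.train_period, scheme.train_trial_set)
    test_side = (scheme.test_role, scheme.test_period, scheme.test_trial_set)
    directions = [(train_side, instance.irrelevant_train, test_side, instance.irrelevant_test)]
    if scheme.bidirectional:
        directions.append(
            (test_side, instance.irrelevant_test, train_side, instance.irrelevant_train)
        )
    accs = []
    for tr_side, tr_irr, te_side, te_irr in directions:
        for held_out in range(n_splits):
            train_splits = [s for s in range(n_splits) if s != held_out]
            X_tr, y_tr = _gather(periods, tr_side, tr_irr, instance.pair, train_splits)
            X_te, y_te = _gather(periods, te_side, te_irr, instance.pair, [held_out])
            accs.append(decode_once(X_tr, y_tr, X_te, y_te))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# scheme-level results


@dataclass
class DecodingResult:
    """Accuracy for one (participant, ROI, scheme)."""

    scheme: str
    trial_set: str
    accuracy: float
    n_pair_instances: int
    chance: float = CHANCE
    participant_id: str = "sub-01"
    roi: str = "roi"
    per_instance: tuple[float, ...] = field(default=(), repr=False)


def run_scheme(
    patterns: BetaPatternSet,
    scheme: DecodingScheme | str,
    trial_set: str = "with_distractors",
) -> DecodingResult:
    """Decode one scheme: average :func:`rotate_and_average` over all pair
    instances."""
    if isinstance(scheme, str):
        scheme = get_scheme(scheme, trial_set=trial_set)
    needed = {scheme.train_period, scheme.test_period}
    periods = {p: average_period(patterns, p) for p in needed}
    instances = enumerate_pair_instances(scheme)
    accs = [rotate_and_average(periods, scheme, inst) for inst in instances]
    return DecodingResult(
        scheme=scheme.name,
        trial_set=scheme.test_trial_set,
        accuracy=float(np.mean(accs)),
        n_pair_instances=len(instances),
        participant_id=patterns.participant_id,
        roi=patterns.roi,
        per_instance=tuple(accs),
    )


@dataclass
class RatioResult:
    """Cross-decoding ratio (cross - 0.5) / (within - 0.5)."""

    ratio: float
    valid: bool
    within: float
    cross: float


def cross_ratio(
    within: DecodingResult | float,
    cross: DecodingResult | float,
    eps: float = 0.01,
) -> RatioResult:
    """The generalization index: 1 = cross-decoding as good as within,
    0 = no generalization.  Flagged invalid (never dropped) when the
    within-decoding margin over chance is <= ``eps``."""
    w = within.accuracy if isinstance(within, DecodingResult) else float(within)
    c = cross.accuracy if isinstance(cross, DecodingResult) else float(cross)
    valid = (w - CHANCE) > eps
    ratio = (c - CHANCE) / (w - CHANCE) if w != CHANCE else np.nan
    return RatioResult(ratio=float(ratio), valid=bool(valid), within=w, cross=c)


def sector_average(values_by_roi: dict[str, float]) -> dict[str, float]:
    """Unweighted mean of ROI-level values within each sector; decoding is
    run per ROI first so large ROIs do not dominate."""
    out: dict[str, float] = {}
    for sector, rois in SECTORS.items():
        members = [values_by_roi[r] for r in rois if r in values_by_roi]
        if members:
            out[sector] = float(np.mean(members))
    if not out:
        raise ValueError("no ROI maps to any sector")
    return out
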