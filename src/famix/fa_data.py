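"""Fatty-acid signature data: containers, CSV I/O, calibration coefficients, tracer selection.

Fatty-acid (FA) signatures are proportional compositions — percent of total
identified FAs in a tissue sample. Diet-mixing analyses need three tables:
consumer profiles (one row per individual), source summaries (per-prey mean
and SD per FA) and calibration coefficients (CCs, one multiplicative factor
per FA describing trophic modification from prey to predator tissue).
Multiplying source values by their CCs takes them to "predator space", after
which the additive trophic-modification term of a mixing model can be set to
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FAProfile",
    "ConsumerDataset",
    "SourceSummary",
    "CCSet",
    "FAClassTable",
    "read_consumer_csv",
    "write_consumer_csv",
    "read_source_csv",
    "write_source_csv",
    "read_cc_csv",
    "write_cc_csv",
    "simulate_consumers_from_summary",
    "compute_ccs",
    "apply_ccs",
    "select_fas",
    "DEFAULT_SUM_TOLERANCE",
]

#: Tolerated deviation of a raw empirical profile's row sum from 100 (percentage
#: points). Published tables routinely omit trace FAs, so a small shortfall is
#: normal.
DEFAULT_SUM_TOLERANCE = 2.0


def _clean_names(names) -> list[str]:
    out = [str(n).strip() for n in names]
    seen = set()
    for n in out:
        if n in seen:
            raise ValueError(f"duplicate FA name {n!r}")
        seen.add(n)
    return out


@dataclass
class FAProfile:
    """One individual's proportional FA signature.

    Parameters
    ----------
    fa_names : sequence of str
        Ordered FA identifiers, e.g. ``"16:1n-7"``.
    values : array-like
        Percent of total identified FAs, one entry per name in ``fa_names``.
    subject_id : str
        Opaque individual label.
    factor_labels : dict
        Categorical design labels, e.g. ``{"day": "21"}``.
    """

    fa_names: list[str]
    values: np.ndarray
    subject_id: str = ""
    factor_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.fa_names = _clean_names(self.fa_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.fa_names),):
            raise ValueError("values length does not match fa_names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite FA value in profile {self.subject_id!r}")
        if np.any(self.values < 0):
            raise ValueError(f"negative FA value in profile {self.subject_id!r}")
        self.factor_labels = {str(k): str(v) for k, v in self.factor_labels.items()}

    def check_sum(self, tolerance: float = DEFAULT_SUM_TOLERANCE) -> None:
        """Raise if the profile total is not 100 within ``tolerance`` points."""
        total = float(self.values.sum())
        if abs(total - 100.0) > tolerance:
            raise ValueError(
                f"profile {self.subject_id!r} sums to {total:.2f}, outside "
                f"100 ± {tolerance}"
            )


@dataclass
class ConsumerDataset:
    """A set of consumer FA profiles sharing one FA ordering and factor design."""

    profiles: list[FAProfile]
    factor_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.profiles:
            raise ValueError("dataset needs at least one profile")
        names = self.profiles[0].fa_names
        for p in self.profiles:
            if p.fa_names != names:
                raise ValueError("all profiles must share one fa_names ordering")
            for f in self.factor_names:
                if f not in p.factor_labels:
                    raise ValueError(
                        f"profile {p.subject_id!r} lacks a level for factor {f!r}"
                    )

    @property
    def fa_names(self) -> list[str]:
        return self.profiles[0].fa_names

    @property
    def n(self) -> int:
        return len(self.profiles)

    def to_matrix(self) -> np.ndarray:
        """(n_individuals, n_fas) array of percent values."""
        return np.vstack([p.values for p in self.profiles])

    def factor_values(self, name: str) -> list[str]:
        if name not in self.factor_names:
            raise KeyError(f"unknown factor {name!r}")
        return [p.factor_labels[name] for p in self.profiles]

    def mean_profile(self) -> np.ndarray:
        return self.to_matrix().mean(axis=0)

    def check_sums(self, tolerance: float | None = DEFAULT_SUM_TOLERANCE) -> None:
        if tolerance is None:
            return
        for p in self.profiles:
            p.check_sum(tolerance)

    def restrict(self, fa_names) -> "ConsumerDataset":
        """Dataset restricted to (and reordered as) ``fa_names``."""
        fa_names = _clean_names(fa_names)
        idx = []
        for n in fa_names:
            try:
                idx.append(self.fa_names.index(n))
            except ValueError:
                raise KeyError(f"FA {n!r} not in dataset") from None
        profiles = [
            FAProfile(fa_names, p.values[idx], p.subject_id, dict(p.factor_labels))
            for p in self.profiles
        ]
        return ConsumerDataset(profiles, list(self.factor_names))

    def subset(self, factor: str, level: str) -> "ConsumerDataset":
        keep = [p for p in self.profiles if p.factor_labels.get(factor) == str(level)]
        if not keep:
            raise KeyError(f"no profiles with {factor}={level!r}")
        return ConsumerDataset(keep, list(self.factor_names))

    def to_dataframe(self) -> pd.DataFrame:
        rows = {}
        rows["id"] = [p.subject_id for p in self.profiles]
        for f in self.factor_names:
            rows[f] = [p.factor_labels[f] for p in self.profiles]
        mat = self.to_matrix()
        for j, fa in enumerate(self.fa_names):
            rows[fa] = mat[:, j]
        return pd.DataFrame(rows)


@dataclass
class SourceSummary:
    """Per-source FA summary: mean and SD per FA, in prey or predator space.

    ``space="predator"`` marks sources whose values have been multiplied by
    calibration coefficients (see :func:`apply_ccs`); such summaries need not
    sum to 100.
    """

    source_name: str
    fa_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    space: str = "prey"

    def __post_init__(self):
        self.fa_names = _clean_names(self.fa_names)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != (len(self.fa_names),) or self.sds.shape != self.means.shape:
            raise ValueError("means/sds length must match fa_names")
        if np.any(self.means < 0) or np.any(self.sds < 0):
            raise ValueError(f"negative mean or SD in source {self.source_name!r}")
        if self.space not in ("prey", "predator"):
            raise ValueError("space must be 'prey' or 'predator'")

    def restrict(self, fa_names) -> "SourceSummary":
        idx = [self.fa_names.index(n) for n in _clean_names(fa_names)]
        return SourceSummary(
            self.source_name, list(fa_names), self.means[idx], self.sds[idx], self.space
        )


@dataclass
class CCSet:
    """Per-FA multiplicative calibration coefficients (trophic modification)."""

    fa_names: list[str]
    cc: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.fa_names = _clean_names(self.fa_names)
        self.cc = np.asarray(self.cc, dtype=float)
        if self.cc.shape != (len(self.fa_names),):
            raise ValueError("cc length must match fa_names")
        if np.any(~np.isfinite(self.cc)) or np.any(self.cc <= 0):
            raise ValueError("calibration coefficients must be positive and finite")

    def lookup(self, fa_names) -> np.ndarray:
        """CC values aligned to ``fa_names``; missing FA is an error."""
        out = np.empty(len(fa_names))
        for i, n in enumerate(_clean_names(fa_names)):
            try:
                out[i] = self.cc[self.fa_names.index(n)]
            except ValueError:
                raise KeyError(f"no calibration coefficient for FA {n!r}") from None
        return out

    def restrict(self, fa_names) -> "CCSet":
        return CCSet(list(fa_names), self.lookup(fa_names), self.provenance)


# Classification of common marine FAs by origin, following the
# dietary / extended-dietary convention of quantitative FA signature work:
# "dietary" FAs cannot be synthesised by the consumer, "extended dietary" are
# of both dietary and endogenous origin, and "endogenous" FAs mostly reflect
# the consumer's own biosynthesis. This is replaceable data, not a rule.
_DEFAULT_FA_CLASSES = {
    "14:0": "extended_dietary",
    "14:1n-5": "endogenous",
    "15:0": "extended_dietary",
    "16:0": "endogenous",
    "16:1n-9": "endogenous",
    "16:1n-7": "extended_dietary",
    "16:2n-4": "dietary",
    "16:3n-4": "dietary",
    "16:4n-1": "dietary",
    "17:0": "extended_dietary",
    "18:0": "endogenous",
    "18:1n-9": "extended_dietary",
    "18:1n-7": "extended_dietary",
    "18:2n-6": "dietary",
    "18:3n-3": "dietary",
    "18:4n-3": "dietary",
    "20:0": "endogenous",
    "20:1n-11": "dietary",
    "20:1n-9": "extended_dietary",
    "20:1n-7": "dietary",
    "20:2n-6": "dietary",
    "20:4n-6": "extended_dietary",
    "20:4n-3": "dietary",
    "20:5n-3": "extended_dietary",
    "21:5n-3": "dietary",
    "22:1n-11": "dietary",
    "22:1n-9": "dietary",
    "22:1n-7": "dietary",
    "22:4n-6": "dietary",
    "22:5n-6": "dietary",
    "22:5n-3": "extended_dietary",
    "22:6n-3": "extended_dietary",
}

_FA_CLASS_VALUES = ("dietary", "extended_dietary", "endogenous")


class FAClassTable:
    """Maps FA name -> origin class (dietary / extended_dietary / endogenous)."""

    def __init__(self, classes: dict[str, str]):
        self._classes = {}
        for fa, cls in classes.items():
            if cls not in _FA_CLASS_VALUES:
                raise ValueError(f"unknown FA class {cls!r} for {fa!r}")
            self._classes[str(fa).strip()] = cls

    @classmethod
    def default(cls) -> "FAClassTable":
        """Packaged classification for common marine FAs."""
        return cls(dict(_DEFAULT_FA_CLASSES))

    @classmethod
    def read_csv(cls, path) -> "FAClassTable":
        df = pd.read_csv(path)
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))

    def class_of(self, fa_name: str) -> str:
        try:
            return self._classes[str(fa_name).strip()]
        except KeyError:
            raise KeyError(f"FA {fa_name!r} has no classification entry") from None

    def __contains__(self, fa_name: str) -> bool:
        return str(fa_name).strip() in self._classes

    def __len__(self) -> int:
        return len(self._classes)


# ---------------------------------------------------------------------------
# CSV I/O (comma, UTF-8, "." decimal)
# ---------------------------------------------------------------------------

def read_consumer_csv(
    path,
    factors: tuple[str, ...] | list[str] = (),
    sum_tolerance: float | None = DEFAULT_SUM_TOLERANCE,
) -> ConsumerDataset:
    """Read a wide consumer table: first column subject id, then the declared
    factor columns, then one numeric column per FA.

    Rows whose FA total is outside ``100 ± sum_tolerance`` are rejected;
    pass ``sum_tolerance=None`` to skip the check (e.g. for predator-space
    or simulated tables).
    """
    df = pd.read_csv(path, dtype=str)
    factors = [str(f) for f in factors]
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"declared factor column {f!r} missing from {path}")
    id_col = df.columns[0]
    fa_cols = [c for c in df.columns[1:] if c not in factors]
    if not fa_cols:
        raise ValueError("no FA columns found")
    profiles = []
    for i, row in df.iterrows():
        values = np.empty(len(fa_cols))
        for j, c in enumerate(fa_cols):
            try:
                values[j] = float(row[c])
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric FA value {row[c]!r} at row {i + 1}, column {c!r}"
                ) from None
        profiles.append(
            FAProfile(
                fa_cols,
                values,
                subject_id=str(row[id_col]),
                factor_labels={f: str(row[f]) for f in factors},
            )
        )
    ds = ConsumerDataset(profiles, factors)
    ds.check_sums(sum_tolerance)
    return ds


def write_consumer_csv(dataset: ConsumerDataset, path) -> None:
    dataset.to_dataframe().to_csv(path, index=False)


def read_source_csv(path) -> list[SourceSummary]:
    """Read source summaries. Two layouts are accepted:

    * long — columns ``source, fa, mean, sd``;
    * wide — first column the source name, then ``mean_<FA>`` / ``sd_<FA>``
      column pairs.
    """
    df = pd.read_csv(path)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if {"source", "fa", "mean", "sd"}.issubset(cols):
        out = []
        for name, grp in df.groupby("source", sort=False):
            out.append(
                SourceSummary(
                    str(name),
                    list(grp["fa"].astype(str)),
                    grp["mean"].to_numpy(float),
                    grp["sd"].to_numpy(float),
                )
            )
        return out
    mean_cols = [c for c in cols[1:] if c.startswith("mean_")]
    fa_names = [c[len("mean_"):] for c in mean_cols]
    sd_cols = [f"sd_{n}" for n in fa_names]
    missing = [c for c in sd_cols if c not in cols]
    if not mean_cols or missing:
        raise ValueError(
            "source CSV must be long (source,fa,mean,sd) or wide with "
            "mean_<FA>/sd_<FA> pairs"
        )
    out = []
    for _, row in df.iterrows():
        out.append(
            SourceSummary(
                str(row[cols[0]]),
                fa_names,
                row[mean_cols].to_numpy(float),
                row[sd_cols].to_numpy(float),
            )
        )
    return out


def write_source_csv(sources: list[SourceSummary], path) -> None:
    """Write sources in the long layout (source, fa, mean, sd)."""
    rows = [
        {"source": s.source_name, "fa": fa, "mean": m, "sd": sd}
        for s in sources
        for fa, m, sd in zip(s.fa_names, s.means, s.sds)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cc_csv(path, provenance: str = "") -> CCSet:
    df = pd.read_csv(path)
    return CCSet(list(df.iloc[:, 0].astype(str)), df.iloc[:, 1].to_numpy(float), provenance)


def write_cc_csv(cc: CCSet, path) -> None:
    pd.DataFrame({"fa": cc.fa_names, "cc": cc.cc}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Consumer simulation from published summary statistics
# ---------------------------------------------------------------------------

def simulate_consumers_from_summary(
    means,
    sds,
    n: int,
    seed: int | np.random.Generator,
    fa_names=None,
    factor_labels: dict[str, str] | None = None,
    id_prefix: str = "sim",
    max_redraws: int = 1000,
) -> ConsumerDataset:
    """Draw ``n`` consumer profiles, each FA independently Normal(mean, sd).

    This reproduces the common practice of reconstructing raw consumer rows
    from a published mean/SD table. Negative draws are redrawn per cell
    (truncating at zero would bias the mean more). Rows are *not*
    renormalised to sum to 100.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != sds.shape or means.ndim != 1:
        raise ValueError("means and sds must be 1-D and the same length")
    if np.any(sds < 0):
        raise ValueError("sds must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    if fa_names is None:
        fa_names = [f"FA{j + 1}" for j in range(means.size)]
    rng = np.random.default_rng(seed)
    values = rng.normal(means, sds, size=(n, means.size))
    for _ in range(max_redraws):
        neg = values < 0
        if not neg.any():
            break
        # redraw only the offending cells from their own Normal(mean, sd)
        idx = np.nonzero(neg)
        values[idx] = rng.normal(means[idx[1]], sds[idx[1]])
    else:
        raise RuntimeError("could not draw non-negative FA values; check means/sds")
    profiles = [
        FAProfile(
            list(fa_names),
            values[i],
            subject_id=f"{id_prefix}{i + 1}",
            factor_labels=dict(factor_labels or {}),
        )
        for i in range(n)
    ]
    return ConsumerDataset(profiles, list(factor_labels or {}))


# ---------------------------------------------------------------------------
# Calibration coefficients
# ---------------------------------------------------------------------------

def compute_ccs(
    consumers: ConsumerDataset,
    diet: list[tuple[SourceSummary, float]],
    provenance: str = "",
) -> CCSet:
    """Calibration coefficients from a feeding trial at (near-)complete turnover.

    ``cc_j = mean_consumer_j / sum_d w_d * mu_jd`` where ``w`` are the mass
    proportions of the trial diet. With a single prey this is simply consumer
    mean over prey mean.
    """
    if not diet:
        raise ValueError("diet must list at least one (source, proportion) pair")
    weights = np.array([w for _, w in diet], dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("diet proportions must be non-negative and sum to 1")
    fa_names = consumers.fa_names
    denom = np.zeros(len(fa_names))
    for (src, _), w in zip(diet, weights):
        denom += w * src.restrict(fa_names).means
    cmean = consumers.mean_profile()
    zero = (denom == 0) & (cmean != 0)
    if zero.any():
        bad = [fa_names[j] for j in np.nonzero(zero)[0]]
        raise ZeroDivisionError(
            f"diet mean is zero but consumer mean is not for {bad}; exclude these "
            "FAs before computing CCs"
        )
    cc = np.where(denom == 0, 1.0, cmean / np.where(denom == 0, 1.0, denom))
    if not provenance:
        names = ", ".join(f"{w:.0%} {s.source_name}" for (s, _), w in zip(diet, weights))
        provenance = f"feeding trial on {names}"
    return CCSet(fa_names, cc, provenance)


def average_ccs(cc_sets: list[CCSet], provenance: str = "") -> CCSet:
    """Arithmetic mean of several CC sets over their shared FA names
    (e.g. combining CCs derived from different single-prey trials)."""
    if not cc_sets:
        raise ValueError("need at least one CC set")
    fa_names = cc_sets[0].fa_names
    stacked = np.vstack([c.lookup(fa_names) for c in cc_sets])
    if not provenance:
        provenance = "average of: " + "; ".join(c.provenance or "?" for c in cc_sets)
    return CCSet(fa_names, stacked.mean(axis=0), provenance)


def apply_ccs(sources: list[SourceSummary], cc: CCSet) -> list[SourceSummary]:
    """Take prey-space sources to predator space: mean and SD multiplied by the
    per-FA CC. The CC acts as a deterministic scalar on the source distribution,
    so the SD scales by the same factor. Predator-space values are fed to the
    mixing model with its additive trophic-modification term fixed at zero.
    """
    out = []
    for src in sources:
        if src.space != "prey":
            raise ValueError(f"source {src.source_name!r} is already in predator space")
        f = cc.lookup(src.fa_names)  # KeyError if an FA has no CC
        out.append(
            SourceSummary(
                src.source_name, list(src.fa_names), src.means * f, src.sds * f,
                space="predator",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tracer selection
# ---------------------------------------------------------------------------

def select_fas(
    consumers: ConsumerDataset,
    cc: CCSet,
    classes: FAClassTable | None = None,
    abundance_threshold: float = 0.5,
    cc_max: float = 2.0,
) -> list[str]:
    """Apply the three tracer-selection filters and return retained FA names.

    An FA is kept iff its grand-mean abundance in the consumers exceeds
    ``abundance_threshold`` percent, it is classified dietary or extended
    dietary, and its CC does not exceed ``cc_max`` (a CC above 2 means the
    consumer holds at least twice the prey proportion, pointing to an
    endogenous origin or preferential accrual rather than diet).

    Order follows the consumer table. An empty retained set is an error.
    """
    if classes is None:
        classes = FAClassTable.default()
    grand_mean = consumers.mean_profile()
    ccs = cc.lookup(consumers.fa_names)
    kept = []
    for j, fa in enumerate(consumers.fa_names):
        cls = classes.class_of(fa)  # missing entry -> KeyError
        if (
            grand_mean[j] > abundance_threshold
            and cls in ("dietary", "extended_dietary")
            and ccs[j] <= cc_max
        ):
            kept.append(fa)
    if not kept:
        raise ValueError("no FAs survive the selection filters; no tracers to model")
    return kept
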