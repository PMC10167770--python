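"""Cross-validation of hybrid genomic prediction and accuracy reporting.

Accuracy is the Pearson correlation between observed and predicted hybrid
performance on the validation set, standardized by the square root of the
trait's broad-sense heritability:  r(g_hat, g) = r / sqrt(H).  Schemes:

``fivefold``
    Random five-fold partitions, each fold once as validation set, many
    iterations; each fold x iteration is one replicate.
``tp_size``
    A random training population (TP) of fixed size, the remaining hybrids
    as validation population (VP), repeated.
``common_male`` / ``common_female``
    Single structured splits in which TP and VP share only male or only
    female parents, built from the tester-group layout of the mating
    design.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import rrblup
from .hybrids import HybridDesign, MatingDesign, make_hybrid_design
from .markers import GenotypeMatrix
from .varcomp import broad_sense_heritability, estimate_components, hybrid_means

KINDS = ("fivefold", "tp_size", "common_male", "common_female")


@dataclass
class CVScheme:
    """Cross-validation scheme parameters."""

    kind: str = "fivefold"
    folds: int = 5
    iterations: int = 100
    n_tp: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.kind == "tp_size" and (self.n_tp is None or self.n_tp < 3):
            raise ValueError("tp_size scheme needs n_tp >= 3")


@dataclass
class AccuracyResult:
    """Per-replicate raw correlations and standardized accuracies.

    ``replicates`` has one row per CV replicate (fold x iteration, TP draw,
    or structured split) with columns ``replicate``, ``n_tp``, ``n_vp``,
    ``raw_r`` and ``accuracy``; the reported means are exact means of the
    retained replicate values.
    """

    trait: str
    scheme: str
    model: str
    heritability: float
    replicates: pd.DataFrame

    @property
    def mean_raw(self) -> float:
        return float(self.replicates["raw_r"].mean())

    @property
    def mean_accuracy(self) -> float:
        return float(self.replicates["accuracy"].mean())


def make_folds(
    hybrids: list[str], folds: int, seed: int | np.random.Generator
) -> list[list[str]]:
    """Random partition into ``folds`` subsets with sizes differing by <= 1."""
    if folds > len(hybrids):
        raise ValueError("more folds than hybrids")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    order = rng.permutation(len(hybrids))
    return [
        [hybrids[i] for i in chunk] for chunk in np.array_split(order, folds)
    ]


def standardized_accuracy(
    observed, predicted, heritability: float,
    trait: str = "", scheme: str = "", model: str = "",
) -> AccuracyResult:
    """Pearson correlation of observed vs predicted, divided by sqrt(H)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) != len(pred) or len(obs) < 3:
        raise ValueError("need >= 3 aligned observation/prediction pairs")
    if not 0 < heritability <= 1:
        raise ValueError("heritability must be in (0, 1]")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("zero variance in observed or predicted values")
    raw = float(np.corrcoef(obs, pred)[0, 1])
    rep = pd.DataFrame(
        {
            "replicate": [0],
            "n_tp": [np.nan],
            "n_vp": [len(obs)],
            "raw_r": [raw],
            "accuracy": [raw / np.sqrt(heritability)],
        }
    )
    return AccuracyResult(trait=trait, scheme=scheme or "direct", model=model,
                          heritability=heritability, replicates=rep)


def _fit_and_score(
    y: pd.Series,
    frame_a: pd.DataFrame,
    frame_d: pd.DataFrame,
    tp: list[str],
    vp: list[str],
    model: str,
    heritability: float,
) -> tuple[float, float]:
    y_tp = y.loc[tp]
    if model == "partial":
        fit = rrblup.fit_partial(y_tp, frame_a.loc[tp])
        pred = rrblup.predict(fit, frame_a.loc[vp])
    elif model == "full":
        fit = rrblup.fit_full(y_tp, frame_a.loc[tp], frame_d.loc[tp])
        if fit.model == "full":
            pred = rrblup.predict(fit, frame_a.loc[vp], frame_d.loc[vp])
        else:
            pred = rrblup.predict(fit, frame_a.loc[vp])
    else:
        raise ValueError(f"unknown model {model!r}")
    obs = y.loc[vp].to_numpy()
    est = pred["predicted_phenotype"].to_numpy()
    raw = float(np.corrcoef(obs, est)[0, 1])
    return raw, raw / np.sqrt(heritability)


def _prepare(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    design: MatingDesign,
    traits: list[str] | None,
    het_policy: str,
) -> tuple[HybridDesign, list[str]]:
    if genotypes.has_missing():
        raise ValueError("genotypes must be QC'd and imputed before CV")
    hd = make_hybrid_design(genotypes, design, het_policy=het_policy)
    all_traits = sorted(phenotypes["trait"].unique())
    if traits is None:
        traits = all_traits
    else:
        unknown = set(traits) - set(all_traits)
        if unknown:
            raise KeyError(f"unknown trait(s): {sorted(unknown)}")
    return hd, traits


def _trait_heritability(
    phenotypes: pd.DataFrame, trait: str, override: float | None
) -> float:
    if override is not None:
        if not 0 < override <= 1:
            raise ValueError("heritability override must be in (0, 1]")
        return float(override)
    vc = estimate_components(phenotypes, trait)
    h = broad_sense_heritability(vc)
    if h <= 0:
        raise ValueError(
            f"estimated heritability for {trait!r} is zero; pass an explicit "
            "heritability to standardize accuracies"
        )
    return h


def run_cv(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    design: MatingDesign,
    scheme: CVScheme,
    model: str = "partial",
    traits: list[str] | None = None,
    het_policy: str = "expected",
    heritability: float | None = None,
) -> dict[str, AccuracyResult]:
    """Run a random cross-validation scheme for each trait.

    Heritability for standardization is estimated once per trait from the
    full phenotype table unless ``heritability`` overrides it (useful when
    the table cannot support the trial model).  The whole RNG stream is
    determined by ``scheme.seed``, so results are bit-reproducible.
    """
    if scheme.kind not in ("fivefold", "tp_size"):
        raise ValueError("run_cv handles fivefold/tp_size; see relatedness_cv")
    hd, traits = _prepare(phenotypes, genotypes, design, traits, het_policy)
    frame_a, frame_d = hd.k_a_frame(), hd.k_d_frame()
    hybrids = hd.hybrids
    if scheme.kind == "tp_size" and scheme.n_tp >= len(hybrids):
        raise ValueError("n_tp must be smaller than the hybrid count")

    results: dict[str, AccuracyResult] = {}
    for trait in traits:
        h = _trait_heritability(phenotypes, trait, heritability)
        y = hybrid_means(phenotypes, trait).reindex(hybrids)
        trait_key = zlib.crc32(trait.encode()) % 2**31
        rng = np.random.default_rng(
            np.random.SeedSequence(scheme.seed, spawn_key=(trait_key,))
        )
        rows = []
        rep_id = 0
        for _ in range(scheme.iterations):
            if scheme.kind == "fivefold":
                folds = make_folds(hybrids, scheme.folds, rng)
                splits = [
                    (sorted(set(hybrids) - set(fold)), fold) for fold in folds
                ]
            else:
                order = rng.permutation(len(hybrids))
                tp = sorted(hybrids[i] for i in order[: scheme.n_tp])
                vp = sorted(hybrids[i] for i in order[scheme.n_tp:])
                splits = [(tp, vp)]
            for tp, vp in splits:
                if len(tp) < 3:
                    raise ValueError("training population smaller than 3")
                raw, acc = _fit_and_score(y, frame_a, frame_d, tp, vp, model, h)
                rows.append(
                    {
                        "replicate": rep_id,
                        "n_tp": len(tp),
                        "n_vp": len(vp),
                        "raw_r": raw,
                        "accuracy": acc,
                    }
                )
                rep_id += 1
        results[trait] = AccuracyResult(
            trait=trait,
            scheme=f"{scheme.kind}(folds={scheme.folds}, n_tp={scheme.n_tp})",
            model=model,
            heritability=h,
            replicates=pd.DataFrame(rows),
        )
    return results


def relatedness_split(
    design: MatingDesign,
    kind: str,
    seed: int = 0,
    tp_size: int | None = None,
    holdout_tester: str | None = None,
) -> tuple[list[str], list[str]]:
    """Structured TP/VP split sharing only male or only female parents.

    ``common_male``: the validation population is every hybrid of one
    held-out female tester and the training population is the hybrids of
    the remaining testers, so TP and VP share pollinator (male) parents but
    no females.  By default the held-out tester is the one whose group size
    is closest to the mean group size (first in design order on ties).

    ``common_female``: a pollinator subset is chosen (seeded greedy draw)
    so that its hybrids across all testers total ``tp_size`` (default: the
    largest tester-group size); those hybrids form the TP and the rest the
    VP, so both sides share the female testers but no males.
    """
    t = design.table
    groups = t.groupby("female", sort=False)["hybrid"].apply(list)
    if kind == "common_male":
        if len(groups) < 2:
            raise ValueError("common-male split needs >= 2 tester groups")
        if holdout_tester is None:
            sizes = groups.apply(len)
            holdout_tester = (sizes - sizes.mean()).abs().idxmin()
        elif holdout_tester not in groups.index:
            raise KeyError(f"unknown tester {holdout_tester!r}")
        vp = list(groups.loc[holdout_tester])
        tp = [h for h in t["hybrid"] if h not in set(vp)]
        if not tp or not vp:
            raise ValueError("common-male split leaves an empty TP or VP")
        tp_males = set(t.loc[t["hybrid"].isin(tp), "male"])
        vp_males = set(t.loc[t["hybrid"].isin(vp), "male"])
        if not tp_males & vp_males:
            raise ValueError(
                "training and validation sets share no male parents; "
                "a common-male split is not possible for this design"
            )
        return tp, vp
    if kind == "common_female":
        counts = t.groupby("male", sort=False)["hybrid"].count()
        if tp_size is None:
            tp_size = int(t.groupby("female", sort=False)["hybrid"].count().max())
        if not 0 < tp_size < len(t):
            raise ValueError("tp_size must be in (0, number of hybrids)")
        rng = np.random.default_rng(seed)
        males = list(counts.index)
        order = [males[i] for i in rng.permutation(len(males))]
        chosen: list[str] = []
        total = 0
        for male in order:
            c = int(counts.loc[male])
            if total + c <= tp_size:
                chosen.append(male)
                total += c
            if total == tp_size:
                break
        if total != tp_size:
            raise ValueError(
                f"no pollinator subset reaches a TP of exactly {tp_size} hybrids"
            )
        chosen_set = set(chosen)
        tp = t.loc[t["male"].isin(chosen_set), "hybrid"].tolist()
        vp = t.loc[~t["male"].isin(chosen_set), "hybrid"].tolist()
        if not vp:
            raise ValueError("common-female split leaves an empty VP")
        tp_females = set(t.loc[t["hybrid"].isin(tp), "female"])
        vp_females = set(t.loc[t["hybrid"].isin(vp), "female"])
        if not tp_females & vp_females:
            raise ValueError(
                "training and validation sets share no female parents; "
                "a common-female split is not possible for this design"
            )
        return tp, vp
    raise ValueError(f"unknown relatedness kind {kind!r}")


def relatedness_cv(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    design: MatingDesign,
    kind: str,
    model: str = "partial",
    traits: list[str] | None = None,
    seed: int = 0,
    tp_size: int | None = None,
    holdout_tester: str | None = None,
    het_policy: str = "expected",
    heritability: float | None = None,
) -> dict[str, AccuracyResult]:
    """Accuracy under a structured common-male or common-female split."""
    hd, traits = _prepare(phenotypes, genotypes, design, traits, het_policy)
    frame_a, frame_d = hd.k_a_frame(), hd.k_d_frame()
    tp, vp = relatedness_split(
        design, kind, seed=seed, tp_size=tp_size, holdout_tester=holdout_tester
    )
    results: dict[str, AccuracyResult] = {}
    for trait in traits:
        h = _trait_heritability(phenotypes, trait, heritability)
        y = hybrid_means(phenotypes, trait).reindex(hd.hybrids)
        raw, acc = _fit_and_score(y, frame_a, frame_d, tp, vp, model, h)
        rep = pd.DataFrame(
            {
                "replicate": [0],
                "n_tp": [len(tp)],
                "n_vp": [len(vp)],
                "raw_r": [raw],
                "accuracy": [acc],
            }
        )
        results[trait] = AccuracyResult(
            trait=trait,
            scheme=f"{kind}(n_tp={len(tp)}, n_vp={len(vp)})",
            model=model,
            heritability=h,
            replicates=rep,
        )
    return results


def accuracy_gain(series) -> int:
    """Percent accuracy change from the first to the last entry of a
    TP-size series, rounded half away from zero to an integer.

    Accepts a sequence of :class:`AccuracyResult` (mean accuracies used)
    or plain numbers ordered by increasing TP size.
    """
    values = [
        s.mean_accuracy if isinstance(s, AccuracyResult) else float(s)
        for s in series
    ]
    if len(values) < 2:
        raise ValueError("need at least two accuracies ordered by TP size")
    first, last = values[0], values[-1]
    if first == 0:
        raise ValueError("first accuracy is zero: percent gain undefined")
    pct = 100.0 * (last - first) / first
    return int(np.floor(pct + 0.5)) if pct >= 0 else int(np.ceil(pct - 0.5))
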