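"""Model/results objects for class-restricted epitope prediction.

`EpitopeClassifier` is built from a panel of annotated antigens and a
labeling configuration; `fit()` decomposes the panel into frame-shifted
k-mers (k 3-15, stride 1 by default), labels them under the chosen rule,
featurizes them into the 33-attribute matrix, rebalances the classes with
SMOTE and grows the decision tree.  The returned `EpitopeResults` carries
the tree and everything needed to score new antigens: per-residue tracks,
region calls, attribute importances, a text `summary()`, and bit-exact
save/load.

Typical use::

    antigens = epiclass.read_fasta("panel.fasta")
    epiclass.read_regions("regions.tsv", antigens)
    model = EpitopeClassifier(antigens)
    res = model.fit(seed=17)
    print(res.summary())
    track = res.predict_track(antigens[0])
    calls = res.call_regions(antigens[0], cutoff=0.2)
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation, features, kmers, scoring, smote, tree
from .io import Antigen, ScoreTrack, read_fasta, read_regions


@dataclasses.dataclass
class FitConfig:
    tree_params: tree.TreeParams = dataclasses.field(default_factory=tree.TreeParams)
    use_smote: bool = True
    smote_config: smote.SmoteConfig = dataclasses.field(default_factory=smote.SmoteConfig)
    target_ratio: float = 1.0
    kmer_cutoff: float = 0.5  # k-mer-level probability cutoff
    region_cutoff: float = 0.2  # sequence-level score cutoff
    seed: int = 0


class EpitopeClassifier:
    """Decision-tree epitope classifier over k-mer physicochemical profiles."""

    def __init__(
        self,
        antigens: Sequence[Antigen],
        rule: kmers.LabelingRule | str = "majority",
        k_min: int = 3,
        k_max: int = 15,
        step: int = 1,
        include_length: bool = False,
    ) -> None:
        if isinstance(rule, str):
            rule = kmers.LabelingRule(name=rule)
        self.antigens = list(antigens)
        self.rule = rule
        self.k_min, self.k_max, self.step = k_min, k_max, step
        self.include_length = include_length
        self.attribute_names = list(features.ATTRIBUTE_NAMES) + (
            ["length"] if include_length else []
        )

    @classmethod
    def from_files(cls, fasta_path, regions_path, **kwargs) -> "EpitopeClassifier":
        antigens = read_fasta(fasta_path)
        read_regions(regions_path, antigens)
        return cls(antigens, **kwargs)

    # -- training data ------------------------------------------------------

    def _sequences(self, antigens: Sequence[Antigen] | None = None) -> dict[str, str]:
        return {ag.id: ag.sequence for ag in (antigens or self.antigens)}

    def build_training_matrix(
        self, antigens: Sequence[Antigen] | None = None
    ) -> tuple[np.ndarray, np.ndarray, list[kmers.Kmer]]:
        """Labeled (X, y, kmers) over epitope/nonepitope k-mers (unassigned dropped)."""
        antigens = list(antigens or self.antigens)
        labeled = kmers.build_labeled_set(
            antigens, self.rule, self.k_min, self.k_max, self.step
        )
        kept = [km for km in labeled if km.label != "unassigned"]
        if not kept:
            raise ValueError("no labeled k-mers; check region annotations")
        X = features.kmer_feature_matrix(kept, self._sequences(antigens), self.include_length)
        y = np.array([km.label == "epitope" for km in kept])
        return X, y, kept

    # -- fitting -------------------------------------------------------------

    def fit(self, config: FitConfig | None = None, **overrides) -> "EpitopeResults":
        if config is None:
            config = FitConfig(**overrides)
        elif overrides:
            raise ValueError("pass either a FitConfig or keyword overrides, not both")
        X, y, kept = self.build_training_matrix()
        if config.use_smote and 0 < y.sum() < len(y):
            X_bal, y_bal = smote.rebalance(
                X, y, config.smote_config, config.target_ratio, seed=config.seed
            )
        else:
            X_bal, y_bal = X, y
        fitted = tree.train_tree(X_bal, y_bal, self.attribute_names, config.tree_params)
        return EpitopeResults(
            model=self,
            tree_=fitted,
            config=config,
            n_kmers=len(kept),
            n_epitope_kmers=int(y.sum()),
            n_balanced=len(y_bal),
            train_X=X_bal,
            train_y=y_bal,
        )

    # -- cross-validation ----------------------------------------------------

    def cross_validate(
        self,
        folds: int = 10,
        seed: int = 0,
        group_by_antigen: bool = True,
        config: FitConfig | None = None,
    ) -> pd.DataFrame:
        """Per-fold held-out metrics; SMOTE and training on training folds only.

        With ``group_by_antigen`` (default) all k-mers of one antigen stay in
        one fold and held-out performance is measured per residue on the
        held-out antigens' score tracks — the honest setting, since k-mers of
        one antigen overlap heavily.  Otherwise k-mer rows are stratified by
        class across folds and metrics are k-mer-level.
        """
        if folds < 2:
            raise ValueError("need at least 2 folds")
        config = config or FitConfig(seed=seed)
        rng = np.random.default_rng(seed)
        rows = []
        if group_by_antigen:
            if len(self.antigens) < folds:
                raise ValueError(f"{len(self.antigens)} antigens cannot fill {folds} folds")
            order = rng.permutation(len(self.antigens))
            assignment = {int(idx): i % folds for i, idx in enumerate(order)}
            for fold in range(folds):
                train = [ag for i, ag in enumerate(self.antigens) if assignment[i] != fold]
                test = [ag for i, ag in enumerate(self.antigens) if assignment[i] == fold]
                sub = EpitopeClassifier(
                    train, self.rule, self.k_min, self.k_max, self.step, self.include_length
                )
                res = sub.fit(config)
                metrics = [
                    evaluation.evaluate_track(
                        res.predict_track(ag),
                        scoring.truth_mask(ag),
                        method="epiclass",
                        policy="default",
                        default_cutoff=config.region_cutoff,
                    ).as_dict()
                    for ag in test
                    if scoring.truth_mask(ag).any() and not scoring.truth_mask(ag).all()
                ]
                if not metrics:
                    continue
                df = pd.DataFrame(metrics).drop(columns=["method", "policy"])
                rows.append({"fold": fold, **df.mean().to_dict()})
        else:
            X, y, _ = self.build_training_matrix()
            idx_pos = rng.permutation(np.flatnonzero(y))
            idx_neg = rng.permutation(np.flatnonzero(~y))
            fold_of = np.empty(len(y), dtype=int)
            fold_of[idx_pos] = np.arange(len(idx_pos)) % folds
            fold_of[idx_neg] = np.arange(len(idx_neg)) % folds
            for fold in range(folds):
                tr, te = fold_of != fold, fold_of == fold
                Xb, yb = X[tr], y[tr]
                if config.use_smote and 0 < yb.sum() < len(yb):
                    Xb, yb = smote.rebalance(
                        Xb, yb, config.smote_config, config.target_ratio, seed=seed + fold
                    )
                t = tree.train_tree(Xb, yb, self.attribute_names, config.tree_params)
                proba = tree.predict_proba(t, X[te])
                cm = evaluation.confusion(proba, y[te], config.kmer_cutoff)
                r = evaluation.rates(*cm)
                auc = evaluation.roc_auc(proba, y[te]) if 0 < y[te].sum() < te.sum() else np.nan
                rows.append({"fold": fold, "cutoff": config.kmer_cutoff, "auc": auc, **r})
        return pd.DataFrame(rows)


@dataclasses.dataclass
class EpitopeResults:
    """Fitted classifier plus training diagnostics."""

    model: EpitopeClassifier
    tree_: tree.TreeNode
    config: FitConfig
    n_kmers: int
    n_epitope_kmers: int
    n_balanced: int
    train_X: np.ndarray | None = None
    train_y: np.ndarray | None = None

    # -- prediction ----------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return tree.predict_proba(self.tree_, X)

    def predict_track(
        self,
        antigen: Antigen,
        kmer_cutoff: float | None = None,
        aggregation: str = "positive_fraction",
    ) -> ScoreTrack:
        """Per-residue score track for one antigen."""
        kms = kmers.generate_kmers(antigen, self.model.k_min, self.model.k_max, self.model.step)
        if not kms:
            return ScoreTrack(antigen.id, [0.0] * len(antigen))
        X = features.kmer_feature_matrix(
            kms, {antigen.id: antigen.sequence}, self.model.include_length
        )
        proba = self.predict_proba(X)
        cutoff = self.config.kmer_cutoff if kmer_cutoff is None else kmer_cutoff
        if aggregation == "positive_fraction":
            return scoring.residue_scores(kms, proba, antigen.id, len(antigen), cutoff)
        if aggregation == "mean_probability":
            return scoring.mean_probability_scores(kms, proba, antigen.id, len(antigen))
        raise ValueError(f"unknown aggregation {aggregation!r}")

    def call_regions(
        self, antigen: Antigen, cutoff: float | None = None, min_length: int = 3
    ) -> list[scoring.RegionCall]:
        track = self.predict_track(antigen)
        cut = self.config.region_cutoff if cutoff is None else cutoff
        return scoring.call_regions(track, cut, min_length)

    # -- diagnostics ---------------------------------------------------------

    def importance(self, n_trees: int = 500, seed: int = 0, max_rows: int | None = 20_000) -> pd.DataFrame:
        """Random-forest importances on (a subsample of) the training matrix."""
        if self.train_X is None:
            raise ValueError("training matrix was not retained")
        X, y = self.train_X, self.train_y
        if max_rows is not None and len(X) > max_rows:
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(X), size=max_rows, replace=False)
            X, y = X[idx], y[idx]
        return tree.forest_importance(
            X, y, self.model.attribute_names, n_trees=n_trees, seed=seed
        )

    def training_accuracy(self) -> float:
        pred = tree.predict(self.tree_, self.train_X, self.config.kmer_cutoff)
        return float(np.mean(pred == self.train_y))

    def summary(self) -> str:
        m = self.model
        lines = [
            "Class-restricted epitope classifier",
            "=" * 51,
            f"{'Antigens:':<28}{len(m.antigens)}",
            f"{'Labeling rule:':<28}{m.rule.name} (threshold {m.rule.threshold})",
            f"{'Kmer range:':<28}{m.k_min}-{m.k_max}, step {m.step}",
            f"{'Attributes:':<28}{len(m.attribute_names)}",
            f"{'Labeled kmers:':<28}{self.n_kmers}",
            f"{'  epitope:':<28}{self.n_epitope_kmers}",
            f"{'  nonepitope:':<28}{self.n_kmers - self.n_epitope_kmers}",
            f"{'Rows after SMOTE:':<28}{self.n_balanced}",
            f"{'Tree nodes:':<28}{self.tree_.n_nodes()}",
            f"{'Tree depth:':<28}{self.tree_.max_depth()}",
            f"{'Kmer cutoff:':<28}{self.config.kmer_cutoff}",
            f"{'Region cutoff:':<28}{self.config.region_cutoff}",
        ]
        if self.train_X is not None:
            lines.append(f"{'Training accuracy:':<28}{self.training_accuracy():.4f}")
        root = self.tree_
        if not root.is_leaf:
            lines.append(
                f"{'Root split:':<28}{root.split_attribute} <= {root.threshold:.4g}"
            )
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "attribute_names": self.model.attribute_names,
            "rule": self.model.rule.name,
            "rule_threshold": self.model.rule.threshold,
            "k_min": self.model.k_min,
            "k_max": self.model.k_max,
            "step": self.model.step,
            "include_length": self.model.include_length,
            "kmer_cutoff": self.config.kmer_cutoff,
            "region_cutoff": self.config.region_cutoff,
            "n_kmers": self.n_kmers,
            "n_epitope_kmers": self.n_epitope_kmers,
            "n_balanced": self.n_balanced,
        }
        tree.save_tree(path, self.tree_, meta)

    @staticmethod
    def load(path) -> "EpitopeResults":
        node, meta = tree.load_tree(path)
        model = EpitopeClassifier(
            antigens=[],
            rule=kmers.LabelingRule(meta["rule"], meta["rule_threshold"]),
            k_min=meta["k_min"],
            k_max=meta["k_max"],
            step=meta["step"],
            include_length=meta["include_length"],
        )
        config = FitConfig(kmer_cutoff=meta["kmer_cutoff"], region_cutoff=meta["region_cutoff"])
        return EpitopeResults(
            model=model,
            tree_=node,
            config=config,
            n_kmers=meta["n_kmers"],
            n_epitope_kmers=meta["n_epitope_kmers"],
            n_balanced=meta["n_balanced"],
        )
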