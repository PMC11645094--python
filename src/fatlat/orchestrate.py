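"""End-to-end experiment driver.

Runs the full analysis on a (typically synthetic) cohort: user-independent
K-fold split of Group A, per-fold standardization statistics from the
training subjects only, adversarial-autoencoder training with KL-based
epoch selection, Group-B fine-tuning, encoding of Group B, cluster indices,
completion-normalized trend regressions, and the assessment table.

Stages write plain CSV/JSON artifacts into the output directory and are
skipped on re-runs when their outputs already exist and the resolved
configuration hash matches (delete an intermediate file to recompute it and
everything downstream of it).

Group B and the validation subjects never contribute to standardization
statistics or model selection; the fold construction makes this structural.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import aae, latent_eval, preprocess, synthio, trend

logger = logging.getLogger("fatlat")

#: scatter colors per activity (latent-space figures)
CLASS_COLORS = {"LungeRight": "green", "LungeLeft": "red",
                "PlankJumpIn": "blue", "Squat": "purple"}


@dataclass
class FoldSplit:
    """User-independent fold: Group-A subjects split into train/validation."""

    fold: int
    train_ids: list[str]
    val_ids: list[str]


def make_folds(subject_ids: list[str], k: int, seed: int) -> list[FoldSplit]:
    """Partition subjects into K near-equal validation blocks (seeded).

    Every subject appears in exactly one validation block; the remaining
    subjects form that fold's training set.
    """
    if k < 2:
        raise ValueError("K must be >= 2")
    if k > len(subject_ids):
        raise ValueError(f"K={k} exceeds {len(subject_ids)} subjects")
    rng = np.random.default_rng(seed)
    order = list(np.array(subject_ids)[rng.permutation(len(subject_ids))])
    blocks = np.array_split(order, k)
    return [FoldSplit(fold=i, train_ids=sorted(set(order) - set(b)),
                      val_ids=sorted(b)) for i, b in enumerate(blocks)]


class TrainingConfig(BaseModel):
    max_epochs: int = 300
    fine_tune_epochs: int = 10
    batch_size: int = 64
    lr: float = 1e-4
    prior_radius: float = 4.0
    prior_sd: float = 1.0
    dropout: float = 0.1
    n_restarts: int = 1


class ExperimentConfig(BaseModel):
    """Resolved configuration of one experiment run."""

    cohort: synthio.GeneratorConfig = Field(default_factory=synthio.GeneratorConfig)
    databases: list[str] = ["DB0", "DB1", "DB2", "DB3", "DB4"]
    variants: list[str] = ["res", "cond"]
    k_folds: int = 4
    seed: int = 0
    alpha: float = trend.ALPHA
    training: TrainingConfig = Field(default_factory=TrainingConfig)

    def model_post_init(self, _ctx) -> None:
        for db in self.databases:
            if db not in preprocess.DATABASES:
                raise ValueError(f"unknown database {db!r}")
        for v in self.variants:
            if v not in ("res", "cond"):
                raise ValueError(f"unknown variant {v!r} (use 'res' or 'cond')")

    def content_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


class Experiment:
    """Stage-wise runner over an output directory (resumable)."""

    def __init__(self, config: ExperimentConfig, out_dir: str | Path):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        hash_file = self.out / "config_hash.txt"
        h = config.content_hash()
        if hash_file.exists() and hash_file.read_text().strip() != h:
            raise ValueError(
                "output directory holds artifacts from a different "
                "configuration; use a fresh directory or delete it")
        hash_file.write_text(h)
        (self.out / "config.json").write_text(config.model_dump_json(indent=1))

    # -- stage 1: cohort --------------------------------------------------

    def simulate(self) -> synthio.Cohort:
        cdir = self.out / "cohort"
        if not (cdir / "manifest.json").exists():
            logger.info("simulate: generating cohort (seed %d)", self.config.cohort.seed)
            manifest, reps = synthio.generate_cohort(self.config.cohort)
            synthio.write_cohort(manifest, reps, cdir)
        return synthio.read_cohort(cdir)

    # -- stage 2: per-fold training + encoding ----------------------------

    def _model_path(self, db: str, variant: str, fold: int) -> Path:
        return self.out / "models" / f"{db}_{variant}_fold{fold}.npz"

    def train_and_encode(self, cohort: synthio.Cohort) -> pd.DataFrame:
        lat_path = self.out / "latents.csv"
        if lat_path.exists():
            return pd.read_csv(lat_path)
        cfg = self.config
        group_a = sorted(p.id for p in cohort.manifest.participants if p.group == "A")
        group_b = sorted(p.id for p in cohort.manifest.participants if p.group == "B")
        folds = make_folds(group_a, cfg.k_folds, cfg.seed)
        (self.out / "models").mkdir(exist_ok=True)
        rows = []
        for db in cfg.databases:
            types = [t for _, t in preprocess.db_channels(db)]
            # run the raw pipeline once per database; only the per-fold
            # standardization statistics differ between folds
            ds_all = preprocess.assemble_dataset(cohort, db)
            X_all, y_all = preprocess.dataset_arrays(ds_all)
            pid_all = np.array([d.participant_id for d in ds_all])
            b_mask = np.isin(pid_all, group_b)
            ds_b = [d for d in ds_all if d.participant_id in group_b]
            for split in folds:
                # standardization from the fold's Group-A training subjects only
                tr_mask = np.isin(pid_all, split.train_ids)
                va_mask = np.isin(pid_all, split.val_ids)
                stats = preprocess.compute_standardization(X_all[tr_mask], types)
                (self.out / "models" / f"{db}_fold{split.fold}_stats.json").write_text(
                    stats.to_json(fold=split.fold, training_subjects=split.train_ids))
                X_tr, y_tr = stats.transform(X_all[tr_mask]), y_all[tr_mask]
                X_va, y_va = stats.transform(X_all[va_mask]), y_all[va_mask]
                X_b, y_b = stats.transform(X_all[b_mask]), y_all[b_mask]
                for variant in cfg.variants:
                    mpath = self._model_path(db, variant, split.fold)
                    if mpath.exists():
                        model = aae.AdversarialAutoencoder.load(mpath)
                    else:
                        logger.info("train: %s %s fold %d", db, variant, split.fold)
                        model = aae.AdversarialAutoencoder(
                            conditional=(variant == "cond"),
                            lr=cfg.training.lr, batch_size=cfg.training.batch_size,
                            max_epochs=cfg.training.max_epochs,
                            prior_radius=cfg.training.prior_radius,
                            prior_sd=cfg.training.prior_sd,
                            dropout=cfg.training.dropout,
                            n_restarts=cfg.training.n_restarts,
                            random_state=synthio.child_seed(cfg.seed, db, variant,
                                                            split.fold),
                        )
                        model.fit(X_tr, y_tr, X_val=X_va, y_val=y_va)
                        model.stats_provenance_ = {"fold": split.fold, "db": db}
                        model.val_accuracy_pre_ft_ = model.score(X_va, y_va)
                        if cfg.training.fine_tune_epochs > 0:
                            model.fine_tune(X_b, y_b,
                                            epochs=cfg.training.fine_tune_epochs)
                        model.save(mpath)
                    acc = model.score(X_va, y_va)
                    acc_pre = getattr(model, "val_accuracy_pre_ft_", acc)
                    z = model.transform(X_b, y_b)
                    for d, (z1, z2) in zip(ds_b, z):
                        rows.append({
                            "participant": d.participant_id, "exercise": d.exercise,
                            "set": d.set_index, "rep": d.rep_index,
                            "z1": float(z1), "z2": float(z2),
                            "fold": split.fold, "variant": variant, "db": db,
                            "val_accuracy": acc, "val_accuracy_pre_ft": acc_pre,
                        })
        latents = pd.DataFrame(rows)
        latents.to_csv(lat_path, index=False)
        return latents

    # -- stage 3: indices / trends / assessment ---------------------------

    def indices(self, latents: pd.DataFrame) -> pd.DataFrame:
        path = self.out / "indices.csv"
        if path.exists():
            return pd.read_csv(path, keep_default_na=True)
        frames = []
        for db, g in latents.groupby("db"):
            idx = latent_eval.index_table_from_latents(g)
            idx["db"] = db
            frames.append(idx)
        out = pd.concat(frames, ignore_index=True)
        out.to_csv(path, index=False)
        return out

    def trends(self, indices: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        tpath, epath, apath = (self.out / f"{n}.csv"
                               for n in ("trends", "ensemble", "assessment"))
        if tpath.exists() and epath.exists() and apath.exists():
            return pd.read_csv(tpath), pd.read_csv(epath), pd.read_csv(apath)
        trends_l, ens_l, assess_l = [], [], []
        for db, g in indices.groupby("db"):
            std = trend.standardize_per_participant(g)
            t = trend.trend_table(std)
            e = trend.ensemble_table(std)
            a = trend.assessment(t, e, alpha=self.config.alpha)
            for df in (t, e, a):
                df.insert(0, "db", db)
            trends_l.append(t)
            ens_l.append(e)
            assess_l.append(a)
        t, e, a = (pd.concat(x, ignore_index=True) for x in (trends_l, ens_l, assess_l))
        t.to_csv(tpath, index=False)
        e.to_csv(epath, index=False)
        a.to_csv(apath, index=False)
        (self.out / "assessment.json").write_text(
            json.dumps(a.to_dict(orient="records"), indent=1))
        return t, e, a

    # -- stage 4: figures --------------------------------------------------

    def figures(self, latents: pd.DataFrame) -> list[Path]:
        fig_dir = self.out / "figures"
        fig_dir.mkdir(exist_ok=True)
        layout = aae.PriorLayout(radius=self.config.training.prior_radius,
                                 sd=self.config.training.prior_sd)
        paths = []
        for (db, variant), g in latents.groupby(["db", "variant"]):
            g0 = g[g["fold"] == g["fold"].min()]
            path = fig_dir / f"latent_{db}_{variant}.png"
            if not path.exists():
                acc = float(g0["val_accuracy"].iloc[0])
                plot_latent_space(g0, layout, acc, path,
                                  title=f"{db} {variant}")
            paths.append(path)
        return paths

    def run(self) -> pd.DataFrame:
        cohort = self.simulate()
        latents = self.train_and_encode(cohort)
        idx = self.indices(latents)
        _, _, assessment = self.trends(idx)
        self.figures(latents)
        return assessment


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> pd.DataFrame:
    """Run (or resume) the full pipeline; returns the assessment table."""
    return Experiment(config, out_dir).run()


def plot_latent_space(latents: pd.DataFrame, layout: aae.PriorLayout,
                      accuracy: float, path: str | Path,
                      title: str = "") -> Path:
    """Scatter of latent points colored by activity with prior modes marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for c, name in enumerate(layout.class_names):
        g = latents[latents["exercise"] == name]
        if len(g) == 0:
            warnings.warn(f"no points for class {name}; legend entry suppressed")
            continue
        ax.scatter(g["z1"], g["z2"], s=8, alpha=0.6,
                   color=CLASS_COLORS.get(name, "gray"), label=name)
        mx, my = layout.mode(c)
        ax.plot(mx, my, "k+", markersize=12)
    ax.legend(fontsize=8)
    ax.set_xlabel("z1")
    ax.set_ylabel("z2")
    ax.set_title(f"{title}  accuracy={accuracy:.2f}".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def plot_trend_grid(std_indices: pd.DataFrame, trends: pd.DataFrame,
                    path: str | Path, alpha: float = trend.ALPHA) -> Path:
    """Grid of index-vs-completion regressions (rows = exercises)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = trend.add_completion(std_indices)
    exercises = sorted(df["exercise"].unique())
    indices = [i for i in latent_eval.INDEX_NAMES if i in set(df["index"])]
    fig, axes = plt.subplots(len(exercises), len(indices),
                             figsize=(3 * len(indices), 2.4 * len(exercises)),
                             squeeze=False)
    for r, ex in enumerate(exercises):
        for c, name in enumerate(indices):
            ax = axes[r][c]
            g = df[(df["exercise"] == ex) & (df["index"] == name)]
            ax.scatter(g["completion"], g["value"], s=6, alpha=0.5)
            row = trends[(trends["exercise"] == ex) & (trends["index"] == name)]
            if len(row) and np.isfinite(row["slope"].iloc[0]):
                row = row.iloc[0]
                xs = np.array([0.0, 100.0])
                color = "green" if row["p_value"] < alpha else "red"
                ax.plot(xs, row["intercept"] + row["slope"] * xs, color=color)
                ax.set_title(f"b={row['slope']:.3f} R2={row['r2']:.2f} "
                             f"p={row['p_value']:.3g}", fontsize=7, color=color)
            if r == len(exercises) - 1:
                ax.set_xlabel("completion %")
            if c == 0:
                ax.set_ylabel(ex, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)
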