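"""End-to-end design run: train generators, sample, filter, assemble, score.

Stage order mirrors the design funnel: sample Key 2 cores and keep the
rigid ones that fit a core pharmacophore; sample Value 2 fragments and
keep the warhead-bearing ones; assemble Key 1 cores and sample Value 1
substituents per core, keeping the top-k most data-like; cross everything
into per-Key-2 candidate matrices; pharmacophore-screen the assembled
candidates; summarize novelty (substructure census) and chemical space
(PCA). Every stage draws its seed from the run seed by a fixed offset and
records input/survivor counts in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemspace, filters, seq2seq
from .assembly import CandidateMatrix, build_candidate_matrix
from .chem import Fragment, Molecule, Role, WarheadPattern, matches_warhead, read_molecules
from .errors import AssemblyError, ConfigError, StageError
from .fixtures import FixtureSpec, generate_library
from .fragmentation import FragmentationConfig, build_sarms
from .pharmacophore import (
    Feature,
    FeatureType,
    PharmacophoreModel,
    cap_attachment_points,
    fit,
    generate_conformers,
    model_from_conformer,
    perceive_features,
)

_STAGE_SEED_OFFSETS = {
    "train_key2": 11, "train_value2": 12, "train_value1": 13,
    "sample_key2": 21, "sample_value2": 22, "sample_value1": 23,
    "conformers": 31, "pca": 41,
}


def stage_seed(base: int, stage: str, extra: int = 0) -> int:
    return (base * 1009 + _STAGE_SEED_OFFSETS.get(stage, 99) + extra) % (2 ** 31 - 1)


@dataclass
class RunConfig:
    """Configuration of a full design run.

    Sampling defaults are the published schedule (50,000 Key 2 at T=2.0,
    10,000 Value 2 at T=2.0, 2,000 Value 1 per Key 1 at T=1.5, top 100
    Value 1); ``scale`` multiplies all three counts for desk-scale runs.
    """

    fixture: FixtureSpec = field(default_factory=FixtureSpec)
    train: seq2seq.TrainConfig = field(default_factory=seq2seq.TrainConfig)
    pretrain_path: str | None = None
    finetune_path: str | None = None
    n_key2: int = 50_000
    t_key2: float = 2.0
    n_value2: int = 10_000
    t_value2: float = 2.0
    n_value1: int = 2_000
    t_value1: float = 1.5
    scale: float = 1.0
    top_k: int = 100
    key2_top: int = 18
    fit_threshold: float = 0.6
    n_conformers: int = 10
    pharmfit_max: int = 50
    max_pairs: int = 4000
    warhead_smarts: str = WarheadPattern().smarts
    exclude_amides: bool = True
    shared_columns: bool = True
    key2_model_path: str | None = None
    compound_model_path: str | None = None
    input_key2: str | None = None
    seed: int = 7

    def __post_init__(self):
        if not (0 < self.scale <= 1):
            raise ConfigError("scale must be in (0, 1]")
        for attr in ("key2_model_path", "compound_model_path",
                     "pretrain_path", "finetune_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{attr} does not exist: {p}")

    def scaled(self, n: int) -> int:
        return max(1, int(round(n * self.scale)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        fixture = FixtureSpec(**data.pop("fixture", {}))
        tc = data.pop("train", {})
        for key in ("pretrain_epochs", "finetune_epochs"):
            if key in tc:
                tc[key] = {Role(k.upper()): v for k, v in tc[key].items()}
        train = seq2seq.TrainConfig(**tc)
        return cls(fixture=fixture, train=train, **data)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, Role):
                return o.value
            raise TypeError
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def desk_config(seed: int = 7, scale: float = 0.1) -> RunConfig:
    """Desk-scale configuration used by the worked examples: a ~1000
    compound synthetic library, compact generators and reduced epochs so a
    full run finishes in minutes on one CPU. The sampling funnel keeps the
    published shape (many Key 2 emissions, few warhead-bearing Value 2
    survivors) at a tenth of the published sampling volume."""
    train = seq2seq.TrainConfig(
        pretrain_epochs={Role.KEY2: 3, Role.VALUE2: 2, Role.VALUE1: 3},
        finetune_epochs={Role.KEY2: 40, Role.VALUE2: 150, Role.VALUE1: 50},
        latent_dim=96, embedding_dim=48, seed=seed, learning_rate=4e-3,
    )
    return RunConfig(train=train, scale=scale, seed=seed, max_pairs=2500,
                     pharmfit_max=40, n_conformers=8)


def _dedupe_pairs(pairs, cap, rng):
    if len(pairs) <= cap:
        return pairs
    idx = sorted(rng.choice(len(pairs), size=cap, replace=False))
    return [pairs[i] for i in idx]


class _Manifest:
    def __init__(self, config: RunConfig):
        self.data = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "stages": [],
            "counts": {},
        }

    def stage(self, name: str, n_in: int, n_out: int, seconds: float, seed=None):
        self.data["stages"].append({
            "stage": name, "n_in": int(n_in), "n_out": int(n_out),
            "seconds": round(seconds, 3), "seed": seed,
        })
        self.data["counts"][name] = int(n_out)

    def require(self, name: str, survivors: int):
        if survivors == 0:
            raise StageError(name, self.data)


def _build_key2_model(config: RunConfig, input_key2: Fragment,
                      warhead: WarheadPattern) -> PharmacophoreModel:
    """3-feature core model (aromatic / HBA / HBD) from a conformer of the
    reference Key 2, standing in for a structure-derived hinge model."""
    capped = cap_attachment_points(input_key2)
    confs = generate_conformers(capped, 1, stage_seed(config.seed, "conformers"))
    return model_from_conformer(
        confs.molecule, confs.conformers[0], radius=1.5,
        types={FeatureType.AROMATIC, FeatureType.HBA, FeatureType.HBD},
        max_features=3,
    )


def _build_compound_model(config: RunConfig, reference: Molecule,
                          warhead: WarheadPattern) -> PharmacophoreModel:
    """6-feature compound model (2 HBA + HBD + residue bonding point
    required, up to 2 hydrophobic optional) from a reference compound."""
    confs = generate_conformers(reference, 1, stage_seed(config.seed, "conformers", 1))
    feats = perceive_features(confs.molecule, confs.conformers[0], warhead)
    chosen = []
    for ftype, want in ((FeatureType.HBA, 2), (FeatureType.HBD, 1),
                        (FeatureType.RESIDUE_BONDING_POINT, 1)):
        got = [p for t, p in feats if t == ftype][:want]
        chosen.extend((ftype, p, False) for p in got)
    hydro = [p for t, p in feats if t == FeatureType.HYDROPHOBIC][:2]
    chosen.extend((FeatureType.HYDROPHOBIC, p, True) for p in hydro)
    return PharmacophoreModel(features=tuple(
        Feature(t, tuple(map(float, p)), 1.5, optional)
        for t, p, optional in chosen
    ))


def _fit_fragment(frag: Fragment, model: PharmacophoreModel, config: RunConfig,
                  warhead: WarheadPattern, extra_seed: int) -> float:
    try:
        capped = cap_attachment_points(frag)
        confs = generate_conformers(capped, config.n_conformers,
                                    stage_seed(config.seed, "conformers", 2 + extra_seed))
        return fit(confs, model, warhead=warhead).best_score
    except Exception:
        return 0.0


def run_design(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full design pipeline; returns (and optionally writes)
    the run manifest. Raises :class:`StageError` if any stage empties."""
    warhead = WarheadPattern(smarts=config.warhead_smarts)
    frag_config = FragmentationConfig(warhead=warhead)
    manifest = _Manifest(config)
    rng = np.random.default_rng(config.seed)

    # -- data ---------------------------------------------------------------
    t0 = time.time()
    if config.pretrain_path and config.finetune_path:
        pretrain, _ = read_molecules(config.pretrain_path)
        finetune, _ = read_molecules(config.finetune_path)
    else:
        pretrain, finetune = generate_library(config.fixture)
    manifest.stage("data", 0, len(pretrain) + len(finetune), time.time() - t0)

    t0 = time.time()
    sarms_pre = build_sarms(pretrain, frag_config)
    sarms_fine = build_sarms(finetune, frag_config)
    manifest.stage("sarms", len(pretrain), len(sarms_pre), time.time() - t0)
    manifest.require("sarms", len(sarms_pre) and len(sarms_fine))

    # -- generators ---------------------------------------------------------
    models: dict[Role, seq2seq.GeneratorModel] = {}
    for kind in (Role.KEY2, Role.VALUE2, Role.VALUE1):
        t0 = time.time()
        tc = replace(config.train, seed=stage_seed(config.seed, f"train_{kind.value.lower()}"))
        pairs_pre = _dedupe_pairs(seq2seq.make_training_pairs(sarms_pre, kind),
                                  config.max_pairs, rng)
        model = seq2seq.train(pairs_pre, tc, "pretrain", kind=kind)
        pairs_fine = _dedupe_pairs(seq2seq.make_training_pairs(sarms_fine, kind),
                                   config.max_pairs, rng)
        model = seq2seq.train(pairs_fine, tc, "finetune", base=model)
        models[kind] = model
        manifest.stage(f"train_{kind.value.lower()}",
                       len(pairs_pre) + len(pairs_fine), 1, time.time() - t0)

    # -- reference input ----------------------------------------------------
    if config.input_key2 is not None:
        input_key2 = Fragment.from_smiles(config.input_key2, Role.KEY2)
    else:
        biggest = max(sarms_fine, key=lambda m: (len(m.compound_ids()), m.key2.smiles))
        input_key2 = biggest.key2

    # -- Key 2 funnel -------------------------------------------------------
    t0 = time.time()
    n_req = config.scaled(config.n_key2)
    seed_k2 = stage_seed(config.seed, "sample_key2")
    sampled_key2 = seq2seq.sample(models[Role.KEY2], input_key2, n_req,
                                  config.t_key2, seed_k2)
    manifest.stage("sample_key2", n_req, len(sampled_key2.fragments),
                   time.time() - t0, seed_k2)
    manifest.require("sample_key2", len(sampled_key2.fragments))

    t0 = time.time()
    rot = filters.rotatable_bond_filter([g.fragment for g in sampled_key2.fragments],
                                        config.exclude_amides)
    score_of = {g.fragment.smiles: g.score for g in sampled_key2.fragments}
    manifest.stage("rotatable_filter", rot.input_count, len(rot.passed), time.time() - t0)
    manifest.require("rotatable_filter", len(rot.passed))

    t0 = time.time()
    if config.key2_model_path:
        key2_model = PharmacophoreModel.load(config.key2_model_path)
    else:
        key2_model = _build_key2_model(config, input_key2, warhead)
    fits = {
        f.smiles: _fit_fragment(f, key2_model, config, warhead, i)
        for i, f in enumerate(rot.passed)
    }
    passing = [f for f in rot.passed if fits[f.smiles] >= config.fit_threshold]
    manifest.stage("key2_pharmacophore", len(rot.passed), len(passing), time.time() - t0)
    manifest.require("key2_pharmacophore", len(passing))

    prioritized = sorted(passing, key=lambda f: (-fits[f.smiles], f.smiles))[:config.key2_top]
    manifest.stage("key2_prioritized", len(passing), len(prioritized), 0.0)

    # -- Value 2 funnel -----------------------------------------------------
    t0 = time.time()
    n_req = config.scaled(config.n_value2)
    seed_v2 = stage_seed(config.seed, "sample_value2")
    sampled_v2 = seq2seq.sample(models[Role.VALUE2], input_key2, n_req,
                                config.t_value2, seed_v2)
    manifest.stage("sample_value2", n_req, len(sampled_v2.fragments),
                   time.time() - t0, seed_v2)
    manifest.require("sample_value2", len(sampled_v2.fragments))

    t0 = time.time()
    wh_report = filters.warhead_filter([g.fragment for g in sampled_v2.fragments], warhead)
    v2_scores = {g.fragment.smiles: g.score for g in sampled_v2.fragments}
    manifest.stage("warhead_filter", wh_report.input_count, len(wh_report.passed),
                   time.time() - t0)
    manifest.require("warhead_filter", len(wh_report.passed))
    value2s = [(f, v2_scores[f.smiles]) for f in wh_report.passed]

    # -- Value 1 sampling and candidate matrices ----------------------------
    from .assembly import assemble_key1

    matrices: list[CandidateMatrix] = []
    n_v1_req = config.scaled(config.n_value1)
    t0 = time.time()
    total_v1 = 0
    for ki, key2 in enumerate(prioritized):
        value1s_per_key1: dict[str, list[tuple[Fragment, float]]] = {}
        for vi, (v2, _) in enumerate(value2s):
            try:
                key1 = assemble_key1(key2, v2)
            except AssemblyError:
                continue  # unjoinable (Key 2, Value 2) combination
            if key1.smiles in value1s_per_key1:
                continue
            seed_v1 = stage_seed(config.seed, "sample_value1", ki * 1000 + vi)
            sampled_v1 = seq2seq.sample(models[Role.VALUE1], key1, n_v1_req,
                                        config.t_value1, seed_v1)
            value1s_per_key1[key1.smiles] = [
                (g.fragment, g.score) for g in sampled_v1.fragments
            ]
            total_v1 += len(sampled_v1.fragments)
        matrix = build_candidate_matrix(
            (key2, score_of.get(key2.smiles, 0.0)), value2s, value1s_per_key1,
            top_k=config.top_k, shared_columns=config.shared_columns,
        )
        if matrix.cells:
            matrices.append(matrix)
    candidates = [c for m in matrices for c in m.candidates()]
    manifest.stage("candidates", total_v1, len(candidates), time.time() - t0)
    manifest.require("candidates", len(candidates))

    # -- compound pharmacophore screen --------------------------------------
    t0 = time.time()
    if config.compound_model_path:
        compound_model = PharmacophoreModel.load(config.compound_model_path)
    else:
        reference = max(finetune, key=lambda m: m.id)
        compound_model = _build_compound_model(config, reference, warhead)
    ranked = sorted(candidates, key=lambda c: (c.cumulative_score, c.molecule.smiles))
    to_fit = ranked[:config.pharmfit_max]
    for i, cand in enumerate(to_fit):
        try:
            confs = generate_conformers(cand.molecule, config.n_conformers,
                                        stage_seed(config.seed, "conformers", 500 + i))
            cand.pharmacophore_fit = fit(confs, compound_model, warhead=warhead).best_score
        except Exception:
            cand.pharmacophore_fit = 0.0
    passing_cands = [c for c in to_fit if c.pharmacophore_fit >= config.fit_threshold]
    manifest.stage("compound_pharmacophore", len(to_fit), len(passing_cands),
                   time.time() - t0)

    # -- novelty census and chemical space ----------------------------------
    t0 = time.time()
    reference_sets = {"pretrain": pretrain, "finetune": finetune}
    census = {}
    for key2 in prioritized:
        try:
            census[key2.smiles] = filters.substructure_census(key2, reference_sets)
        except Exception:
            census[key2.smiles] = None
    n_novel = sum(1 for v in census.values()
                  if v is not None and all(c == 0 for c in v.values()))
    manifest.stage("census", len(prioritized), n_novel, time.time() - t0)

    t0 = time.time()
    cand_mols = [c.molecule for c in candidates]
    all_mols = pretrain + finetune + cand_mols
    labels = (["pretrain"] * len(pretrain) + ["finetune"] * len(finetune)
              + ["candidate"] * len(cand_mols))
    fp = chemspace.fingerprint(all_mols)
    proj = chemspace.project(fp, labels)
    focus = {
        "finetune": chemspace.mean_intragroup_distance(proj, "finetune"),
        "pretrain": chemspace.mean_intragroup_distance(proj, "pretrain"),
    }
    manifest.stage("pca", len(all_mols), len(all_mols), time.time() - t0)
    manifest.data["focus"] = focus
    manifest.data["counts"]["warhead_positive_candidates"] = sum(
        1 for c in candidates if matches_warhead(c.molecule, warhead))

    # -- exports ------------------------------------------------------------
    if out_dir is not None:
        out = Path(out_dir)
        (out / "matrices").mkdir(parents=True, exist_ok=True)
        rows = []
        for n, c in enumerate(candidates):
            rows.append({
                "id": f"C{n + 1:05d}", "key2": c.key2.smiles, "value2": c.value2.smiles,
                "value1": c.value1.smiles, "smiles": c.molecule.smiles,
                "cumulative_score": c.cumulative_score,
                "pharmacophore_fit": c.pharmacophore_fit,
            })
        pd.DataFrame(rows).to_csv(out / "candidates.csv", index=False)
        for n, m in enumerate(matrices):
            blob = {
                "key2": m.key2.smiles,
                "rows": [f.smiles for f in m.rows],
                "columns": [f.smiles for f in m.columns],
                "cells": [
                    {"row": i, "col": j, "smiles": c.molecule.smiles,
                     "score": c.cumulative_score}
                    for (i, j), c in sorted(m.cells.items())
                ],
            }
            (out / "matrices" / f"matrix_{n:02d}.json").write_text(json.dumps(blob, indent=1))
        pd.DataFrame({
            "id": fp.ids, "label": labels,
            "pc1": proj.coordinates[:, 0], "pc2": proj.coordinates[:, 1],
        }).to_csv(out / "pca.csv", index=False)
        (out / "census.json").write_text(json.dumps(census, indent=1))
        (out / "manifest.json").write_text(json.dumps(manifest.data, indent=1))
    return manifest.data
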