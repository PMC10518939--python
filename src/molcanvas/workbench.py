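"""Fixture corpora, dataset I/O and end-to-end pipelines.

Everything needed to exercise the canvas-rewriting model without a
download: a packaged list of drug-like molecules, a random-SELFIES corpus
generator whose outputs decode to valid molecules by construction, the
top-fraction property filter with the conditional-training pipeline, and
a learning-curve runner that evaluates saved epoch checkpoints.

Desk-scale model defaults (2 layers, width 128) live in
:func:`desk_config`; the mechanism under study is scale-free, so these
small models exercise every code path of the full-size configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import chem, metrics
from ._packaged_data import PACKAGED_SMILES
from .blm import BlankLanguageModel
from .metrics import MetricReport, MoleculeSet, PropertySummary


def desk_config(**overrides) -> dict:
    """Estimator parameters for desk-scale runs (2 layers, width 128)."""
    cfg = dict(n_layers=2, d_model=128, n_heads=4, batch_size=32,
               learning_rate=1e-3, n_epochs=4, max_len=160, max_actions=100)
    cfg.update(overrides)
    return cfg


# ---------------------------------------------------------------------------
# Fixture corpora
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a fixture corpus."""
    n_molecules: int
    seed: int = 0
    source: str = "packaged_list"     # or "random_selfies"
    max_tokens: int = 24

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.source not in ("packaged_list", "random_selfies"):
            raise ValueError(f"unknown source {self.source!r}")


def fixture_corpus(spec: FixtureSpec) -> MoleculeSet:
    """A seeded fixture corpus of SMILES strings.

    ``packaged_list`` draws (without replacement) from the bundled
    drug-like list; ``random_selfies`` derives random token sequences in
    the robust-string dialect — always starting with an atom token, so
    every sequence decodes to a valid molecule — and returns their SMILES.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.source == "packaged_list":
        if spec.n_molecules > len(PACKAGED_SMILES):
            raise ValueError(
                f"packaged list has {len(PACKAGED_SMILES)} molecules; "
                f"{spec.n_molecules} requested (no replacement)")
        idx = rng.permutation(len(PACKAGED_SMILES))[:spec.n_molecules]
        return MoleculeSet([PACKAGED_SMILES[i] for i in sorted(idx)],
                           role="training")
    return MoleculeSet([_random_selfies_smiles(rng, spec.max_tokens)
                        for _ in range(spec.n_molecules)], role="training")


def _random_selfies_smiles(rng: np.random.Generator, max_tokens: int) -> str:
    from .selfies_codec import alphabet, decode

    # organic-leaning token mix: chains grow instead of terminating on
    # saturated halogens, so sizes spread like small drug-like molecules
    atoms = ["[C]"] * 10 + ["[N]", "[O]"] * 2 + \
        ["[=C]", "[=O]", "[=N]", "[S]", "[F]", "[Cl]", "[Br]"]
    alpha = alphabet()
    n = int(rng.integers(4, max_tokens + 1))
    toks = ["[C]"]
    for _ in range(n - 1):
        if rng.random() < 0.8:
            toks.append(str(rng.choice(atoms)))
        else:
            toks.append(str(rng.choice(alpha)))
    smiles = decode(toks)
    assert smiles, "a sequence starting with an atom token always decodes"
    return smiles


def to_representation(smiles_list: Sequence[str], representation: str
                      ) -> list[str]:
    """Re-express SMILES strings in a training representation."""
    rep = representation.upper()
    if rep == "SMILES":
        return list(smiles_list)
    if rep == "SELFIES":
        from .selfies_codec import encode
        return [encode(s) for s in smiles_list]
    if rep == "DEEPSMILES":
        from .deepsmiles_codec import to_deepsmiles
        return [to_deepsmiles(s) for s in smiles_list]
    raise ValueError(f"unknown representation {representation!r}")


# ---------------------------------------------------------------------------
# Property filtering and conditional training
# ---------------------------------------------------------------------------

def property_filter_top_fraction(corpus, prop: str, fraction: float,
                                 property_fn: Callable[[str], float | None]
                                 | None = None) -> MoleculeSet:
    """Molecules in the top ``fraction`` by property value.

    Sorts descending and keeps ceil(fraction * n); molecules the adapter
    cannot score are excluded (their count is not part of n).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    strings = (corpus.molecules if isinstance(corpus, MoleculeSet)
               else list(corpus))
    if property_fn is None:
        property_fn = lambda m: chem.compute_property(m, prop)  # noqa: E731
    scored = [(m, property_fn(m)) for m in strings]
    scored = [(m, v) for m, v in scored if v is not None]
    if not scored:
        raise ValueError(f"property {prop!r} computable for no molecule")
    scored.sort(key=lambda mv: -mv[1])
    keep = math.ceil(fraction * len(scored))
    return MoleculeSet([m for m, _ in scored[:keep]], role="training")


@dataclass
class ConditionalRun:
    """Result of property-biased training: three property summaries and
    the generated set's median distances to the whole/biased sets."""
    property: str
    fraction: float
    whole: PropertySummary
    biased: PropertySummary
    generated: PropertySummary
    n_sampled: int
    n_incomplete: int
    model: BlankLanguageModel

    @property
    def distance_to_whole(self) -> float:
        return abs(self.generated.median - self.whole.median)

    @property
    def distance_to_biased(self) -> float:
        return abs(self.generated.median - self.biased.median)

    @property
    def shifted_toward_biased(self) -> bool:
        return self.distance_to_biased < self.distance_to_whole


def conditional_pipeline(corpus, prop: str, n_samples: int,
                         fraction: float = 0.5,
                         representation: str = "SMILES",
                         model_params: dict | None = None,
                         property_fn: Callable[[str], float | None]
                         | None = None,
                         seed: int = 0) -> ConditionalRun:
    """Train on the top-fraction subset and compare property distributions.

    The generator is trained only on molecules whose property is in the
    top ``fraction`` of the corpus; the property distributions of the
    whole corpus, the biased subset and the generated set are summarized
    so the shift toward the biased set can be measured (the success
    criterion is generated-median closer to the biased median than to the
    whole-corpus median).
    """
    strings = (corpus.molecules if isinstance(corpus, MoleculeSet)
               else list(corpus))
    biased = property_filter_top_fraction(strings, prop, fraction,
                                          property_fn)
    params = desk_config(**(model_params or {}))
    model = BlankLanguageModel(representation=representation, seed=seed,
                               **params)
    model.fit(to_representation(biased.molecules, representation))
    results = model.sample(n_samples, seed=seed + 1)
    complete = [r.text for r in results if r.complete]
    n_incomplete = len(results) - len(complete)
    gen_smiles = [m for m in metrics.decode_molecules(complete, representation)
                  if m]
    if not gen_smiles:
        raise ValueError("generation yielded no decodable molecules")
    summarize = lambda ms: metrics.property_distribution(  # noqa: E731
        ms, prop, property_fn=property_fn)
    return ConditionalRun(
        property=prop, fraction=fraction,
        whole=summarize(strings), biased=summarize(biased.molecules),
        generated=summarize(gen_smiles),
        n_sampled=n_samples, n_incomplete=n_incomplete, model=model)


# ---------------------------------------------------------------------------
# Learning curves
# ---------------------------------------------------------------------------

def learning_curve(corpus, checkpoint_epochs: Sequence[int], n_samples: int,
                   reference=None, representation: str = "SMILES",
                   model_params: dict | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Train once, snapshot at the listed epochs, evaluate each snapshot.

    For every checkpoint the model generates ``n_samples`` molecules and
    the table reports validity, unique@k, internal diversity and (when a
    held-out reference is given) scaffold similarity.
    """
    checkpoint_epochs = sorted(set(checkpoint_epochs))
    if not checkpoint_epochs:
        raise ValueError("checkpoint list must be non-empty")
    strings = (corpus.molecules if isinstance(corpus, MoleculeSet)
               else list(corpus))
    params = desk_config(**(model_params or {}))
    params["n_epochs"] = max(params.get("n_epochs", 0),
                             max(checkpoint_epochs))
    model = BlankLanguageModel(representation=representation, seed=seed,
                               **params)
    model.fit(to_representation(strings, representation),
              snapshot_epochs=checkpoint_epochs)
    rows = []
    ref = None if reference is None else (
        reference.molecules if isinstance(reference, MoleculeSet)
        else list(reference))
    for epoch in checkpoint_epochs:
        snap = model.snapshots_[epoch]
        from .sampler import GenerationConfig, generate_batch
        res = generate_batch(snap, n_samples,
                             GenerationConfig(seed=seed + epoch))
        complete = [r.text for r in res if r.complete]
        row = {"epoch": epoch, "n_samples": n_samples,
               "n_incomplete": n_samples - len(complete),
               "loss": model.loss_history_[epoch - 1]}
        if complete:
            k = min(1000, len(complete))
            row["validity"] = metrics.validity(complete, representation)
            row[f"unique@{k}"] = metrics.uniqueness_at_k(
                complete, k, representation)
            valid = [m for m in metrics.decode_molecules(
                complete, representation) if chem.is_valid(m)]
            if valid:
                row["int_div"] = metrics.int_div(valid)
                if ref is not None:
                    row["scaf"] = metrics.scaf_similarity(valid, ref)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------

def read_molecule_file(path, format: str = "txt",
                       smiles_column: str = "SMILES",
                       strict: bool = False) -> MoleculeSet:
    """Read molecules from plain text (one per line) or CSV.

    Blank lines and CRLF endings are tolerated; in strict mode a line the
    chemistry adapter rejects aborts with its line number, otherwise it is
    kept (validity is a metric, not an I/O concern).
    """
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path)
        if smiles_column not in df.columns:
            raise ValueError(f"column {smiles_column!r} not in {path}")
        lines = [(i + 2, str(s)) for i, s in enumerate(df[smiles_column])]
    elif format == "txt":
        with open(path, newline="") as fh:
            lines = [(i + 1, ln.strip()) for i, ln in enumerate(fh)]
        lines = [(no, ln) for no, ln in lines if ln]
    else:
        raise ValueError(f"unknown format {format!r}")
    if strict:
        for no, ln in lines:
            if not chem.is_valid(ln):
                raise ValueError(f"{path}:{no}: invalid molecule {ln!r}")
    return MoleculeSet([ln for _, ln in lines], role="training")


def write_molecule_file(molecules: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(molecules) + "\n")


def write_report(report: MetricReport | dict, path) -> None:
    """JSON report: metric name -> {value, parameters, n}."""
    payload = report.to_dict() if isinstance(report, MetricReport) else report
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
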