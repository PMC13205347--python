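"""Self-contained synthetic molecule--spectrum benchmark generator.

Real molecule--spectrum matching corpora pair experimentally acquired ¹H
and ¹³C NMR spectra with small organic molecules.  This module emulates
that regime end to end so every stage of the matcher is trainable and
testable without external data:

* molecules — random connected C/N/O heavy-atom graphs (≤16 heavy atoms)
  with valence-respecting bonds (C≤4, N≤3, O≤2) and implicit hydrogens;
* chemical shifts — a deterministic additive-increment surrogate: a base
  shift per (element, hybridization) plus per-neighbor electronegativity
  increments, clamped to the nucleus range (¹H: 2–12.05 ppm, ¹³C:
  2–230 ppm).  Structure determines the spectrum exactly, which is the
  property the matching task needs; the values are not physical predictions;
* images — 256×256 trace renders of Lorentzian peak profiles with seeded
  Gaussian noise and smooth polynomial baseline drift, ppm decreasing
  left-to-right;
* pairs — one positive and one mismatched pair per molecule (1:1),
  molecule-level 8:1:1 train/val/test splits, with the test molecules
  divided into a Test_rand subset (random mismatches) and a Test_diff
  subset (mismatches constrained to low structural similarity).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem

from .molgraph import (MolecularGraph, canonical_smiles, morgan_fingerprint,
                       smiles_to_graph, validate_molecule)

H_RANGE = (2.0, 12.05)
C_RANGE = (2.0, 230.0)
VALENCE = {"C": 4, "N": 3, "O": 2}


# ----------------------------------------------------------------- sampling

def _random_heavy_graph(rng: np.random.Generator, n: int):
    """Random connected valence-respecting heavy-atom graph (tree + extras)."""
    probs = {"C": 0.70, "N": 0.15, "O": 0.15}
    elements = list(rng.choice(list(probs), size=n, p=list(probs.values())))
    elements[int(rng.integers(n))] = "C"     # guarantee at least one carbon
    used = np.zeros(n, dtype=int)
    bonds: dict[tuple[int, int], int] = {}
    order = list(rng.permutation(n))
    placed = [order[0]]
    for atom in order[1:]:
        hosts = [a for a in placed if used[a] < VALENCE[elements[a]]]
        if not hosts:
            return None
        host = hosts[int(rng.integers(len(hosts)))]
        bonds[(min(atom, host), max(atom, host))] = 1
        used[atom] += 1
        used[host] += 1
        placed.append(atom)
    for _ in range(int(rng.poisson(0.6))):   # ring closures
        free = [a for a in range(n) if used[a] < VALENCE[elements[a]]]
        if len(free) < 2:
            break
        i, j = rng.choice(free, size=2, replace=False)
        key = (min(i, j), max(i, j))
        if key in bonds:
            continue
        bonds[key] = 1
        used[i] += 1
        used[j] += 1
    for _ in range(int(rng.poisson(0.8))):   # bond-order upgrades (C/N sp2)
        cands = [k for k, o in bonds.items()
                 if o == 1 and all(used[a] < VALENCE[elements[a]] and
                                   elements[a] != "O" for a in k)]
        if not cands:
            break
        key = cands[int(rng.integers(len(cands)))]
        bonds[key] = 2
        used[list(key)] += 1
    return elements, bonds


def sample_molecule(rng: np.random.Generator,
                    size_range: tuple[int, int] = (4, 16),
                    max_attempts: int = 100) -> MolecularGraph:
    """Draw one random valid molecule; passes :func:`validate_molecule`."""
    lo, hi = size_range
    if lo < 1 or hi > 16 or lo > hi:
        raise ValueError(f"size_range {size_range} outside [1, 16]")
    for _ in range(max_attempts):
        n = int(rng.integers(lo, hi + 1))
        built = _random_heavy_graph(rng, n)
        if built is None:
            continue
        elements, bonds = built
        mol = Chem.RWMol()
        for el in elements:
            mol.AddAtom(Chem.Atom(el))
        for (i, j), order in bonds.items():
            mol.AddBond(int(i), int(j),
                        Chem.BondType.DOUBLE if order == 2 else Chem.BondType.SINGLE)
        try:
            m = mol.GetMol()
            Chem.SanitizeMol(m)
        except Exception:
            continue
        graph = smiles_to_graph(Chem.MolToSmiles(m))
        ok, _ = validate_molecule(graph)
        if ok:
            return graph
    raise RuntimeError(f"could not sample a valid molecule in {max_attempts} tries")


def sample_molecules(n: int, seed: int,
                     size_range: tuple[int, int] = (4, 16)) -> list[MolecularGraph]:
    """``n`` structurally unique molecules (canonical-SMILES deduplicated)."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[MolecularGraph] = []
    while len(out) < n:
        g = sample_molecule(rng, size_range)
        smi = canonical_smiles(g)
        if smi in seen:
            continue
        seen.add(smi)
        out.append(g)
    return out


# ------------------------------------------------------------------- shifts

@dataclass(frozen=True)
class ShiftModel:
    """Additive-increment surrogate for ¹H/¹³C chemical shifts (ppm)."""

    c_base: dict = field(default_factory=lambda: {
        "sp3": 30.0, "sp2": 130.0, "aromatic": 128.0, "sp": 75.0})
    h_base: dict = field(default_factory=lambda: {
        ("C", "sp3"): 2.2, ("C", "sp2"): 5.8, ("C", "aromatic"): 7.3,
        ("C", "sp"): 2.9, ("N", "any"): 2.8, ("O", "any"): 4.5})
    c_increment: dict = field(default_factory=lambda: {
        "O": 25.0, "N": 12.0, "C": 9.5})
    h_increment: dict = field(default_factory=lambda: {
        "O": 1.2, "N": 0.6, "C": 0.25})


@dataclass
class ShiftTable:
    """Peak lists: ¹³C one peak per carbon; ¹H one peak per proton group."""

    c_peaks: list[tuple[float, float]]   # (ppm, weight=1) per carbon atom
    h_peaks: list[tuple[float, float]]   # (ppm, weight=attached-H count)

    def peaks(self, nucleus: str) -> list[tuple[float, float]]:
        if nucleus not in ("1H", "13C"):
            raise ValueError(f"unknown nucleus {nucleus!r}")
        return self.h_peaks if nucleus == "1H" else self.c_peaks


def _hybrid_label(atom: Chem.Atom) -> str:
    if atom.GetIsAromatic():
        return "aromatic"
    h = atom.GetHybridization()
    return {Chem.HybridizationType.SP: "sp",
            Chem.HybridizationType.SP2: "sp2"}.get(h, "sp3")


def assign_chemical_shifts(graph: MolecularGraph,
                           model: ShiftModel | None = None) -> ShiftTable:
    """Deterministic shift table from structure; clamped to nucleus ranges."""
    model = model or ShiftModel()
    mol = graph.mol if graph.mol is not None else Chem.MolFromSmiles(graph.smiles)
    c_peaks, h_peaks = [], []
    for atom in mol.GetAtoms():
        el = atom.GetSymbol()
        hyb = _hybrid_label(atom)
        neighbors = [n.GetSymbol() for n in atom.GetNeighbors()]
        if el == "C":
            shift = model.c_base[hyb] + sum(
                model.c_increment.get(n, 0.0) for n in neighbors)
            c_peaks.append((float(np.clip(shift, *C_RANGE)), 1.0))
        n_h = atom.GetTotalNumHs()
        if n_h:
            key = (el, hyb) if el == "C" else (el, "any")
            shift = model.h_base[key] + sum(
                model.h_increment.get(n, 0.0) for n in neighbors)
            h_peaks.append((float(np.clip(shift, *H_RANGE)), float(n_h)))
    c_peaks.sort()
    h_peaks.sort()
    return ShiftTable(c_peaks=c_peaks, h_peaks=h_peaks)


# ---------------------------------------------------------------- rendering

@dataclass
class RenderSpec:
    """How a peak list becomes a 256×256 trace image."""

    size: int = 256
    h_halfwidth: float = 0.02    # Lorentzian half-width (ppm), ¹H
    c_halfwidth: float = 0.5     # ppm, ¹³C
    noise_sigma: float = 0.01
    drift_amplitude: float = 0.05
    drift_order: int = 3
    filled: bool = True          # fill the area under the trace

    def ppm_axis(self, nucleus: str) -> np.ndarray:
        """Pixel-column ppm values; ppm decreases left to right."""
        lo, hi = H_RANGE if nucleus == "1H" else C_RANGE
        return np.linspace(hi, lo, self.size)

    def ppm_to_pixel(self, ppm: float, nucleus: str) -> float:
        lo, hi = H_RANGE if nucleus == "1H" else C_RANGE
        return (hi - ppm) / (hi - lo) * (self.size - 1)


def render_profile(table: ShiftTable, nucleus: str,
                   spec: RenderSpec | None = None,
                   supersample: int = 8) -> np.ndarray:
    """Noise-free 1-D intensity profile (max-normalized sum of Lorentzians).

    Peaks can be narrower than one pixel column (a 0.02 ppm ¹H line spans
    ~0.5 px over the 10 ppm range), so the profile is evaluated on a
    ``supersample``-times finer grid and box-averaged down; plain per-pixel
    sampling would alias peak heights with sub-pixel shift changes.
    """
    spec = spec or RenderSpec()
    lo, hi = H_RANGE if nucleus == "1H" else C_RANGE
    n_fine = spec.size * supersample
    axis = np.linspace(hi, lo, n_fine)
    w = spec.h_halfwidth if nucleus == "1H" else spec.c_halfwidth
    profile = np.zeros_like(axis)
    for ppm, weight in table.peaks(nucleus):
        profile += weight * w ** 2 / ((axis - ppm) ** 2 + w ** 2)
    profile = profile.reshape(spec.size, supersample).mean(axis=1)
    peak = profile.max()
    return profile / peak if peak > 0 else profile


def render_spectrum_image(table: ShiftTable, nucleus: str,
                          spec: RenderSpec | None = None,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """256×256 grayscale trace image in [0,1] with noise and baseline drift."""
    spec = spec or RenderSpec()
    rng = rng or np.random.default_rng(0)
    size = spec.size
    profile = render_profile(table, nucleus, spec) if \
        table.peaks(nucleus) else np.zeros(size)
    x = np.linspace(-1, 1, size)
    drift = np.zeros(size)
    for k in range(1, spec.drift_order + 1):
        drift += rng.normal() * x ** k
    peak = np.abs(drift).max()
    drift = drift * (spec.drift_amplitude / peak) if peak > 0 else drift
    signal = np.clip(profile * 0.9 + drift + rng.normal(0, spec.noise_sigma, size),
                     0.0, 1.0)
    img = np.zeros((size, size), dtype=np.float32)
    rows = np.round((1.0 - signal) * (size - 1)).astype(int)
    for col in range(size):
        r0, r1 = rows[col], rows[col - 1] if col else rows[col]
        lo, hi = min(r0, r1), max(r0, r1)
        img[lo:hi + 1, col] = 1.0
        if spec.filled:
            img[rows[col]:, col] = 1.0
    return img


def image_to_input(img: np.ndarray) -> np.ndarray:
    """Grayscale [0,1] image -> (3, H, W) float32 network input."""
    return np.repeat(img[None, :, :], 3, axis=0).astype(np.float32)


def save_png(img: np.ndarray, path) -> None:
    from PIL import Image

    Image.fromarray((np.clip(img, 0, 1) * 255).astype(np.uint8), mode="L").save(path)


def load_png(path, size: int = 256) -> np.ndarray:
    """Load a spectral PNG, bilinear-resize to ``size`` and scale to [0,1]."""
    from PIL import Image

    with Image.open(path) as im:
        im = im.convert("L").resize((size, size), Image.BILINEAR)
        return np.asarray(im, dtype=np.float32) / 255.0


# ------------------------------------------------------------------ dataset

@dataclass
class DatasetManifest:
    """Molecule, spectrum and pair records of one synthetic benchmark."""

    molecules: pd.DataFrame    # mol_id, smiles
    spectra: pd.DataFrame      # mol_id, nucleus, image
    pairs: pd.DataFrame        # pair_id, mol_id, smiles, spec_mol_id,
                               # h_image, c_image, label, neg_mode, split, fallback
    seed: int
    diff_threshold: float

    def split(self, name: str) -> pd.DataFrame:
        return self.pairs[self.pairs["split"] == name].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.pairs.to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "n_molecules": len(self.molecules),
            "n_spectrum_records": len(self.spectra),
            "n_pairs": len(self.pairs),
            "pairs_per_split": self.pairs["split"].value_counts().to_dict(),
        }


def _split_assignment(mol_ids: list[str], seed: int) -> dict[str, str]:
    """Molecule-level 8:1:1 split; test divided into rand/diff halves."""
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(mol_ids)))
    n = len(mol_ids)
    n_train = int(round(0.8 * n))
    n_val = int(round(0.1 * n))
    out: dict[str, str] = {}
    test_ids = order[n_train + n_val:]
    for idx in order[:n_train]:
        out[mol_ids[idx]] = "train"
    for idx in order[n_train:n_train + n_val]:
        out[mol_ids[idx]] = "val"
    # halve the test pool into rand/diff subsets; too-small pools (fewer
    # than 2 molecules per subset) stay entirely in test_rand
    n_test = len(test_ids)
    n_rand = (n_test + 1) // 2 if n_test >= 4 else n_test
    for k, idx in enumerate(test_ids):
        out[mol_ids[idx]] = "test_rand" if k < n_rand else "test_diff"
    return out


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    if n < 2:
        return np.arange(n)
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def build_pair_dataset(molecules: pd.DataFrame, seed: int,
                       diff_threshold: float = 0.2,
                       image_dir: str = "images",
                       fingerprints: dict[str, np.ndarray] | None = None
                       ) -> DatasetManifest:
    """Assemble spectrum and pair records over given molecule records.

    ``molecules`` needs columns ``mol_id`` and ``smiles``.  Each molecule
    contributes two spectrum records (¹H and ¹³C), one positive pair and
    one mismatched pair (1:1), with mismatch partners drawn inside the
    molecule's own split so no structure leaks across splits.  Test_diff
    mismatches must fall below ``diff_threshold`` Tanimoto similarity;
    when no unused candidate qualifies the least-similar one is used and
    flagged in the ``fallback`` column.  Each spectrum pair serves in
    exactly one positive and at most one mismatched pair.
    """
    if len(molecules) < 20:
        raise ValueError("need at least 20 molecules to build pair splits")
    mol_ids = molecules["mol_id"].astype(str).tolist()
    smiles = dict(zip(mol_ids, molecules["smiles"].astype(str)))
    split_of = _split_assignment(mol_ids, seed)
    spectra = pd.DataFrame(
        [(m, nuc, f"{image_dir}/{m}_{nuc}.png")
         for m in mol_ids for nuc in ("1H", "13C")],
        columns=["mol_id", "nucleus", "image"])
    img = {(m, n): f"{image_dir}/{m}_{n}.png" for m in mol_ids
           for n in ("1H", "13C")}
    rng = np.random.default_rng(seed + 1)
    rows = []
    by_split: dict[str, list[str]] = {}
    for m in mol_ids:
        by_split.setdefault(split_of[m], []).append(m)
    for split_name in ("train", "val", "test_rand", "test_diff"):
        members = by_split.get(split_name, [])
        if not members:
            continue
        if len(members) < 2:
            raise ValueError(f"split {split_name!r} has <2 molecules")
        neg_mode = "diff" if split_name == "test_diff" else "rand"
        if neg_mode == "rand":
            partner = {m: members[j] for m, j in
                       zip(members, _derangement(len(members), rng))}
            fallback = {m: False for m in members}
        else:
            partner, fallback = _assign_diff_partners(
                members, smiles, diff_threshold, rng, fingerprints)
        for m in members:
            p = partner[m]
            rows.append((m, split_of[m], smiles[m], m, img[(m, "1H")],
                         img[(m, "13C")], 1, neg_mode, False))
            rows.append((m, split_of[m], smiles[m], p, img[(p, "1H")],
                         img[(p, "13C")], 0, neg_mode, fallback[m]))
    pairs = pd.DataFrame(rows, columns=[
        "mol_id", "split", "smiles", "spec_mol_id", "h_image", "c_image",
        "label", "neg_mode", "fallback"])
    pairs = pairs.sort_values(["split", "mol_id", "label"],
                              ascending=[True, True, False]).reset_index(drop=True)
    pairs.insert(0, "pair_id", [f"p{k:06d}" for k in range(len(pairs))])
    return DatasetManifest(molecules=molecules.copy(), spectra=spectra,
                           pairs=pairs, seed=seed, diff_threshold=diff_threshold)


def _assign_diff_partners(members, smiles, threshold, rng, fingerprints=None):
    """Low-similarity mismatch partners, each used at most once."""
    if fingerprints is None:
        fingerprints = {m: morgan_fingerprint(smiles_to_graph(smiles[m]))
                        for m in members}
    fps = np.stack([fingerprints[m] for m in members]).astype(np.int32)
    inter = fps @ fps.T
    pop = fps.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    idx_partner: dict[int, int] = {}
    fb: dict[int, bool] = {}
    used = np.zeros(len(members), dtype=bool)
    order = rng.permutation(len(members))
    for i in order:
        free = ~used
        free[i] = False
        cand = np.flatnonzero(free & (sim[i] < threshold))
        if len(cand):
            j = int(rng.choice(cand))
            fb[i] = False
        elif free.any():
            pool = np.flatnonzero(free)
            j = int(pool[np.argmin(sim[i][pool])])
            fb[i] = True
        else:
            # the only unused target is i itself: swap with an earlier
            # assignment so every spectrum still serves at most once
            donors = [o for o, j2 in idx_partner.items() if o != i and j2 != i]
            o = min(donors, key=lambda o: sim[i][idx_partner[o]])
            j = idx_partner[o]
            idx_partner[o] = i
            fb[o] = not sim[o, i] < threshold
            fb[i] = not sim[i, j] < threshold
        idx_partner[i] = j
        used[j] = True
    partner = {members[i]: members[j] for i, j in idx_partner.items()}
    fallback = {members[i]: fb[i] for i in idx_partner}
    return partner, fallback


# ------------------------------------------------------------ orchestration

def generate_dataset(n_molecules: int, seed: int,
                     size_range: tuple[int, int] = (4, 16),
                     diff_threshold: float = 0.2,
                     render_spec: RenderSpec | None = None,
                     out_dir=None, render: bool = True):
    """Sample molecules, build the manifest and (optionally) render images.

    Returns ``(manifest, images)`` where ``images`` maps
    ``(mol_id, nucleus)`` to a grayscale [0,1] array (empty when
    ``render=False``).  With ``out_dir`` set, PNGs, ``manifest.csv`` and a
    ``shifts.csv`` sidecar are written there.
    """
    render_spec = render_spec or RenderSpec()
    graphs = sample_molecules(n_molecules, seed, size_range)
    mol_df = pd.DataFrame({
        "mol_id": [f"m{k:06d}" for k in range(len(graphs))],
        "smiles": [canonical_smiles(g) for g in graphs]})
    fps = {mid: morgan_fingerprint(g)
           for mid, g in zip(mol_df["mol_id"], graphs)}
    manifest = build_pair_dataset(mol_df, seed=seed,
                                  diff_threshold=diff_threshold,
                                  fingerprints=fps)
    images: dict[tuple[str, str], np.ndarray] = {}
    shift_rows = []
    if render:
        rng = np.random.default_rng(seed + 2)
        for mid, g in zip(mol_df["mol_id"], graphs):
            table = assign_chemical_shifts(g)
            for nucleus in ("1H", "13C"):
                images[(mid, nucleus)] = render_spectrum_image(
                    table, nucleus, render_spec, rng)
                for ppm, wt in table.peaks(nucleus):
                    shift_rows.append((mid, nucleus, ppm, wt))
    if out_dir is not None:
        import pathlib
        import yaml

        out = pathlib.Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        for (mid, nucleus), img in images.items():
            save_png(img, out / "images" / f"{mid}_{nucleus}.png")
        manifest.to_csv(out / "manifest.csv")
        pd.DataFrame(shift_rows,
                     columns=["mol_id", "nucleus", "ppm", "weight"]
                     ).to_csv(out / "shifts.csv", index=False)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump({"n_molecules": n_molecules, "seed": seed,
                            "size_range": list(size_range),
                            "diff_threshold": diff_threshold}, fh)
    graphs_by_id = dict(zip(mol_df["mol_id"], graphs))
    return manifest, images, graphs_by_id
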