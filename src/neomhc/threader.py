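"""Fixed-backbone peptide/MHC threading, repacking and binding energies.

The protocol mirrors the structure of comparative p/MHC modelling with a
fixed peptide backbone:

1. trim the template complex to the alpha1/alpha2 groove domain (heavy
   chain residues up to 180) plus the peptide;
2. define the groove as every heavy-chain residue with an atom within a
   cutoff (default 3.5 A) of the peptide;
3. thread a target HLA sequence onto the template backbone: a global
   BLOSUM62 alignment maps allele residues onto template positions, and at
   mismatches the side chain is rebuilt from the most probable rotamer
   (alleles whose alignment gaps a groove position are rejected);
4. repack groove + peptide side chains by Metropolis simulated annealing
   over the discrete rotamer library (backbone fixed, fully seeded);
5. score the binding energy dE = E(complex) - E(MHC) - E(peptide), parts
   frozen in their bound coordinates;
6. per allele, repeat the stochastic refinement ``n_models`` times and
   report the mean dE of the ``top_k`` lowest-energy models.

A polyAla mock allele (every groove residue replaced by Ala) serves as the
negative control of the screen.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial.distance import cdist

from neomhc.chemdata import N_CHI, ROTAMER_LIBRARY, VDW_RADII
from neomhc.energy import (AtomTable, EnergyWeights, build_atom_table,
                           energy_breakdown, pair_energy)
from neomhc.sidechain import build_sidechain, mutate_residue, set_rotamer
from neomhc.structure import Residue, StructureModel

logger = logging.getLogger(__name__)


class ThreadingError(ValueError):
    """Raised when an allele cannot be threaded onto the template."""


@dataclasses.dataclass
class TemplateComplex:
    """Groove-trimmed template: heavy-chain groove domain + peptide."""

    structure: StructureModel
    heavy_chain: str
    peptide_chain: str
    groove_resseqs: tuple[int, ...] = ()

    @property
    def heavy_sequence(self) -> str:
        return self.structure.chain(self.heavy_chain).sequence()

    @property
    def peptide_sequence(self) -> str:
        return self.structure.chain(self.peptide_chain).sequence()


@dataclasses.dataclass
class ThreadedModel:
    model: StructureModel
    allele: str
    heavy_chain: str
    peptide_chain: str
    groove_resseqs: tuple[int, ...]
    mutated_resseqs: tuple[int, ...]


@dataclasses.dataclass
class BindingEnergyResult:
    e_complex: float
    e_mhc: float
    e_pep: float
    delta_e: float
    per_residue: dict[tuple[str, int], float]
    model_index: int = 0
    seed: int = 0
    clash_flagged: bool = False


@dataclasses.dataclass
class ScreenResult:
    allele: str
    mean_delta_e: float
    sd_delta_e: float
    deltas: list[float]
    top_k: int
    results: list[BindingEnergyResult]
    status: str = "scored"
    identity: float | None = None


ALPHA12_LAST_RESSEQ = 180


def trim_to_groove(structure: StructureModel, heavy_chain: str,
                   peptide_chain: str) -> TemplateComplex:
    """Drop every chain except heavy + peptide and every heavy-chain
    residue beyond the alpha1/alpha2 domain boundary (resseq > 180)."""
    if not structure.has_chain(heavy_chain):
        raise ThreadingError(f"heavy chain {heavy_chain!r} missing")
    if not structure.has_chain(peptide_chain):
        raise ThreadingError(f"peptide chain {peptide_chain!r} missing")
    heavy = structure.chain(heavy_chain).copy()
    heavy.residues = [r for r in heavy.residues
                      if r.resseq <= ALPHA12_LAST_RESSEQ]
    if not heavy.residues:
        raise ThreadingError("no heavy-chain residues within the groove domain")
    peptide = structure.chain(peptide_chain).copy()
    if not peptide.residues:
        raise ThreadingError("peptide chain has no residues")
    trimmed = StructureModel([heavy, peptide], source=structure.source)
    tc = TemplateComplex(trimmed, heavy_chain, peptide_chain)
    tc.groove_resseqs = groove_residues(tc)
    return tc


def groove_residues(tc: TemplateComplex,
                    cutoff: float = 3.5) -> tuple[int, ...]:
    """Heavy-chain residues with any atom within ``cutoff`` of any peptide
    atom. Deterministic; monotone in the cutoff."""
    pep = tc.structure.chain(tc.peptide_chain)
    pep_coords = np.array([a.coord for r in pep.residues for a in r.atoms])
    if pep_coords.size == 0:
        raise ThreadingError("peptide chain has no atoms")
    groove = []
    for res in tc.structure.chain(tc.heavy_chain).residues:
        coords = np.array([a.coord for a in res.atoms])
        if cdist(coords, pep_coords).min() <= cutoff:
            groove.append(res.resseq)
    return tuple(groove)


def _has_backbone(res: Residue) -> bool:
    return all(res.atom(n) is not None for n in ("N", "CA", "C"))


def _align(template_seq: str, allele_seq: str):
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner.align(template_seq, allele_seq)[0]


def thread_allele(tc: TemplateComplex, allele_seq: str,
                  allele_name: str = "allele") -> ThreadedModel:
    """Thread an HLA sequence onto the fixed template backbone.

    The allele is globally aligned to the template heavy-chain sequence
    (BLOSUM62, gap open/extend 11/1). Matched positions keep the template
    side chain; mismatches are rebuilt from the new residue's most
    probable rotamer; an alignment gap at a groove position rejects the
    allele.
    """
    heavy = tc.structure.chain(tc.heavy_chain)
    template_seq = heavy.sequence()
    alignment = _align(template_seq, allele_seq)
    # template index -> allele residue (None = gap)
    mapping: dict[int, str | None] = {}
    t_blocks, a_blocks = alignment.aligned
    covered = set()
    for (ts, te), (as_, ae) in zip(t_blocks, a_blocks):
        for k in range(te - ts):
            mapping[ts + k] = allele_seq[as_ + k]
            covered.add(ts + k)
    for i in range(len(template_seq)):
        if i not in covered:
            mapping[i] = None
    model = tc.structure.copy()
    new_heavy = model.chain(tc.heavy_chain)
    groove = set(tc.groove_resseqs)
    mutated = []
    for i, res in enumerate(new_heavy.residues):
        target = mapping[i]
        if target is None:
            if res.resseq in groove:
                raise ThreadingError(
                    f"{allele_name}: alignment gap at groove residue "
                    f"{res.resseq}")
            continue
        if target == res.one_letter:
            continue
        if not _has_backbone(res):
            logger.warning("residue %s%d lacks a full backbone; kept as is",
                           res.name, res.resseq)
            continue
        from neomhc.structure import ONE_TO_THREE
        mutate_residue(res, ONE_TO_THREE[target])
        mutated.append(res.resseq)
    return ThreadedModel(model=model, allele=allele_name,
                         heavy_chain=tc.heavy_chain,
                         peptide_chain=tc.peptide_chain,
                         groove_resseqs=tc.groove_resseqs,
                         mutated_resseqs=tuple(mutated))


def thread_polyala(tc: TemplateComplex,
                   allele_name: str = "polyAla") -> ThreadedModel:
    """Mock negative-control allele: every groove residue replaced by Ala
    (including Gly and Pro); residues without a complete backbone are left
    untouched with a warning."""
    model = tc.structure.copy()
    heavy = model.chain(tc.heavy_chain)
    mutated = []
    for res in heavy.residues:
        if res.resseq not in tc.groove_resseqs or res.name == "ALA":
            continue
        if not _has_backbone(res):
            logger.warning("groove residue %s%d lacks a backbone; "
                           "not mutated to Ala", res.name, res.resseq)
            continue
        mutate_residue(res, "ALA")
        mutated.append(res.resseq)
    return ThreadedModel(model=model, allele=allele_name,
                         heavy_chain=tc.heavy_chain,
                         peptide_chain=tc.peptide_chain,
                         groove_resseqs=tc.groove_resseqs,
                         mutated_resseqs=tuple(mutated))


def mutate_peptide(tm: ThreadedModel, position: int, new_restype: str,
                   chis: tuple[float, ...] | None = None) -> ThreadedModel:
    """Substitute one peptide residue (1-based position along the chain)
    on the fixed backbone; used to build self-peptide models."""
    model = tm.model.copy()
    pep = model.chain(tm.peptide_chain)
    if not (1 <= position <= len(pep.residues)):
        raise ValueError(f"peptide position {position} out of range")
    mutate_residue(pep.residues[position - 1], new_restype, chis)
    return dataclasses.replace(
        tm, model=model, allele=f"{tm.allele}/pep{position}{new_restype}")


# --- repacking -----------------------------------------------------------


class RepackContext:
    """Precomputed rotamer interaction tables for one threaded model.

    Candidate 0 of every repackable residue is its current (template or
    threaded) side chain; the rest come from the rotamer library. The MC
    objective is the sum of candidate-vs-fixed-environment energies,
    candidate-vs-candidate pair energies and a small rotamer-prior term.
    The tables depend only on the structure, so one context serves every
    seeded trajectory of the model pool.
    """

    def __init__(self, tm: ThreadedModel,
                 weights: EnergyWeights | None = None,
                 rotamer_lib: dict | None = None,
                 prior_weight: float = 0.3,
                 pair_cutoff: float = 12.0):
        self.tm = tm
        self.weights = weights or EnergyWeights()
        lib = rotamer_lib or ROTAMER_LIBRARY
        self.table = build_atom_table(
            tm.model, {tm.heavy_chain, tm.peptide_chain})
        t = self.table
        groove = set(tm.groove_resseqs)
        self.repack_uids: list[int] = []
        residues: dict[int, Residue] = {}
        uid = -1
        for chain in tm.model.chains:
            for res in chain.residues:
                uid += 1
                residues[uid] = res
                in_scope = (
                    (chain.id == tm.heavy_chain and res.resseq in groove)
                    or chain.id == tm.peptide_chain)
                if (in_scope and N_CHI.get(res.name, 0) > 0
                        and _has_backbone(res)):
                    self.repack_uids.append(uid)
        self.residues = residues
        # candidate side-chain coordinate sets per repackable residue
        self.sc_idx: dict[int, np.ndarray] = {}
        self.candidates: dict[int, list[np.ndarray]] = {}
        self.priors: dict[int, np.ndarray] = {}
        self.probs: dict[int, np.ndarray] = {}
        for uid in self.repack_uids:
            res = residues[uid]
            idx = t.res_indices(uid)
            sc = idx[~t.backbone[idx]]
            self.sc_idx[uid] = sc
            names = [t.atom_names[i] for i in sc]
            backbone = {n: res.atom(n).coord for n in ("N", "CA", "C")}
            cands = [t.coords[sc].copy()]
            rots = lib[res.name]
            best_p = max(p for _, p in rots)
            priors = [-np.log(best_p)]
            probs = [best_p]
            for chis, p in rots:
                coords = build_sidechain(backbone, res.name, chis)
                cands.append(np.array([coords[n] for n in names]))
                priors.append(-np.log(max(p, 1e-6)))
                probs.append(p)
            self.candidates[uid] = cands
            self.priors[uid] = prior_weight * np.array(priors)
            probs = np.array(probs)
            self.probs[uid] = probs / probs.sum()
        # fixed environment = everything except repackable side chains
        all_idx = np.arange(t.n)
        movable = (np.concatenate([self.sc_idx[u] for u in self.repack_uids])
                   if self.repack_uids else np.array([], dtype=int))
        self.env_idx = np.setdiff1d(all_idx, movable)
        # E_self[uid][k]
        self.e_self: dict[int, np.ndarray] = {}
        for uid in self.repack_uids:
            vals = [pair_energy(t, self.sc_idx[uid], self.env_idx,
                                self.weights, coords_a=c)
                    for c in self.candidates[uid]]
            self.e_self[uid] = np.array(vals) + self.priors[uid]
        # E_pair[(u, v)][k, l] for residue pairs that can interact
        self.e_pair: dict[tuple[int, int], np.ndarray] = {}
        ca_coord = {}
        for uid in self.repack_uids:
            res = residues[uid]
            ca = res.atom("CA")
            ca_coord[uid] = ca.coord
        for i, u in enumerate(self.repack_uids):
            for v in self.repack_uids[i + 1:]:
                if np.linalg.norm(ca_coord[u] - ca_coord[v]) > pair_cutoff:
                    continue
                ku, kv = len(self.candidates[u]), len(self.candidates[v])
                mat = np.zeros((ku, kv))
                for a in range(ku):
                    for b in range(kv):
                        # evaluate candidate-b coords against candidate-a
                        # coords: use table override on both sides via a
                        # temporary swap of v's coordinates
                        saved = t.coords[self.sc_idx[v]].copy()
                        t.coords[self.sc_idx[v]] = self.candidates[v][b]
                        mat[a, b] = pair_energy(
                            t, self.sc_idx[u], self.sc_idx[v], self.weights,
                            coords_a=self.candidates[u][a])
                        t.coords[self.sc_idx[v]] = saved
                if np.any(mat != 0.0):
                    self.e_pair[(u, v)] = mat

    def state_energy(self, state: dict[int, int]) -> float:
        e = sum(self.e_self[u][k] for u, k in state.items())
        for (u, v), mat in self.e_pair.items():
            e += mat[state[u], state[v]]
        return float(e)

    def delta_energy(self, state: dict[int, int], uid: int,
                     new_k: int) -> float:
        d = self.e_self[uid][new_k] - self.e_self[uid][state[uid]]
        for (u, v), mat in self.e_pair.items():
            if u == uid:
                d += mat[new_k, state[v]] - mat[state[uid], state[v]]
            elif v == uid:
                d += mat[state[u], new_k] - mat[state[u], state[uid]]
        return float(d)

    def apply_state(self, state: dict[int, int]) -> StructureModel:
        """Write a state's side-chain coordinates into a copy of the
        model (and keep the context's table unchanged)."""
        model = self.tm.model.copy()
        uid = -1
        for chain in model.chains:
            for res in chain.residues:
                uid += 1
                if uid not in state:
                    continue
                coords = self.candidates[uid][state[uid]]
                names = [self.table.atom_names[i] for i in self.sc_idx[uid]]
                for name, coord in zip(names, coords):
                    res.atom(name).coord = coord.copy()
        return model


def repack(context: RepackContext, seed: int,
           t_start: float = 5.0, t_end: float = 0.2,
           sweeps_per_residue: int = 4,
           min_sweeps: int = 15) -> tuple[StructureModel, float]:
    """Metropolis simulated annealing over discrete rotamers.

    Deterministic given the seed; the returned model carries the best
    state visited, so the final objective never exceeds the initial one.
    """
    rng = np.random.default_rng(seed)
    uids = context.repack_uids
    state = {u: 0 for u in uids}
    energy = context.state_energy(state)
    best_state, best_energy = dict(state), energy
    if uids:
        n_sweeps = max(min_sweeps, sweeps_per_residue * len(uids))
        temps = np.geomspace(t_start, t_end, n_sweeps)
        for temp in temps:
            order = rng.permutation(len(uids))
            for oi in order:
                uid = uids[oi]
                n_cand = len(context.candidates[uid])
                if n_cand < 2:
                    continue
                new_k = int(rng.integers(0, n_cand))
                if new_k == state[uid]:
                    continue
                d = context.delta_energy(state, uid, new_k)
                if d <= 0 or rng.random() < np.exp(-d / temp):
                    state[uid] = new_k
                    energy += d
                    if energy < best_energy:
                        best_energy = energy
                        best_state = dict(state)
        # greedy coordinate-descent polish from the best state visited:
        # cycle residues, setting each to its argmin candidate, until no
        # single-residue move improves the objective
        state = dict(best_state)
        improved = True
        guard = 0
        while improved and guard < 50:
            improved = False
            guard += 1
            for uid in uids:
                deltas = [context.delta_energy(state, uid, k)
                          for k in range(len(context.candidates[uid]))]
                k_best = int(np.argmin(deltas))
                if deltas[k_best] < -1e-12:
                    state[uid] = k_best
                    best_energy += deltas[k_best]
                    improved = True
        best_state = state
    model = context.apply_state(best_state)
    return model, float(best_energy)


def exhaustive_repack(context: RepackContext
                      ) -> tuple[dict[int, int], float]:
    """Enumerate every rotamer combination (small systems only); the
    global optimum of the same objective the annealer uses."""
    import itertools
    uids = context.repack_uids
    sizes = [len(context.candidates[u]) for u in uids]
    if np.prod(sizes, dtype=float) > 2e5:
        raise ValueError("state space too large for exhaustive enumeration")
    best_state, best_e = None, np.inf
    for combo in itertools.product(*[range(s) for s in sizes]):
        state = dict(zip(uids, combo))
        e = context.state_energy(state)
        if e < best_e:
            best_e, best_state = e, state
    return best_state, float(best_e)


# --- binding energies ----------------------------------------------------


HARD_CLASH_FRACTION = 0.5


def binding_energy(model: StructureModel, heavy_chain: str,
                   peptide_chain: str,
                   weights: EnergyWeights | None = None,
                   model_index: int = 0, seed: int = 0
                   ) -> BindingEnergyResult:
    """dE = E(complex) - E(MHC) - E(peptide), parts frozen in their bound
    coordinates. The per-residue map (complex minus parts, keyed by
    (chain, resseq)) sums to dE exactly."""
    w = weights or EnergyWeights()
    t_complex = build_atom_table(model, {heavy_chain, peptide_chain})
    e_complex, pr_complex = energy_breakdown(t_complex, w)
    t_mhc = build_atom_table(model, {heavy_chain})
    e_mhc, pr_mhc = energy_breakdown(t_mhc, w)
    t_pep = build_atom_table(model, {peptide_chain})
    e_pep, pr_pep = energy_breakdown(t_pep, w)

    def keyed(table: AtomTable, pr: dict[int, float]
              ) -> dict[tuple[str, int], float]:
        return {(table.chain_of_res[u], table.resseq_of_res[u]): v
                for u, v in pr.items()}

    per = keyed(t_complex, pr_complex)
    for part_table, part_pr in ((t_mhc, pr_mhc), (t_pep, pr_pep)):
        for key, v in keyed(part_table, part_pr).items():
            per[key] = per.get(key, 0.0) - v

    # hard-clash flag on cross-chain contacts
    heavy_mask = np.array([c == heavy_chain for c in t_complex.chain_ids])
    pep_mask = np.array([c == peptide_chain for c in t_complex.chain_ids])
    clash = False
    if heavy_mask.any() and pep_mask.any():
        d = cdist(t_complex.coords[heavy_mask], t_complex.coords[pep_mask])
        r0 = (t_complex.radii[heavy_mask][:, None]
              + t_complex.radii[pep_mask][None, :])
        clash = bool(np.any(d < HARD_CLASH_FRACTION * r0))
        if clash:
            logger.warning("hard steric clash at the interface; LJ clamped")
    return BindingEnergyResult(
        e_complex=e_complex, e_mhc=e_mhc, e_pep=e_pep,
        delta_e=e_complex - e_mhc - e_pep,
        per_residue=per, model_index=model_index, seed=seed,
        clash_flagged=clash,
    )


def screen_allele(tc: TemplateComplex, allele_seq: str | None,
                  allele_name: str = "allele",
                  n_models: int = 100, top_k: int = 10,
                  seed: int = 0,
                  weights: EnergyWeights | None = None,
                  threaded: ThreadedModel | None = None) -> ScreenResult:
    """Run the n-model / top-k protocol for one allele.

    ``threaded`` may be supplied directly (e.g. polyAla or peptide-mutant
    models); otherwise ``allele_seq`` is threaded first. Model seeds are
    spawned deterministically from ``seed``.
    """
    if top_k > n_models:
        raise ValueError("top_k must be <= n_models")
    w = weights or EnergyWeights()
    try:
        tm = threaded if threaded is not None else thread_allele(
            tc, allele_seq, allele_name)
    except ThreadingError as exc:
        logger.warning("allele %s rejected: %s", allele_name, exc)
        return ScreenResult(allele=allele_name, mean_delta_e=np.nan,
                            sd_delta_e=np.nan, deltas=[], top_k=top_k,
                            results=[], status=f"rejected: {exc}")
    context = RepackContext(tm, weights=w)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_models)
    results = []
    for m, s in enumerate(child_seeds):
        model, _ = repack(context, int(s))
        results.append(binding_energy(model, tm.heavy_chain,
                                      tm.peptide_chain, w,
                                      model_index=m, seed=int(s)))
    deltas = np.array([r.delta_e for r in results])
    top = np.sort(deltas)[:top_k]
    return ScreenResult(
        allele=tm.allele if threaded is not None else allele_name,
        mean_delta_e=float(top.mean()),
        sd_delta_e=float(top.std(ddof=1)) if top_k > 1 else 0.0,
        deltas=[float(x) for x in deltas], top_k=top_k, results=results,
    )


def residue_decomposition(screen: ScreenResult,
                          peptide_chain: str) -> dict[int, float]:
    """Mean per-peptide-position dE contribution across the top_k models.
    Anchor positions show up as the minima."""
    if not screen.results:
        raise ValueError("screen result carries no scored models")
    order = np.argsort([r.delta_e for r in screen.results])[:screen.top_k]
    acc: dict[int, list[float]] = {}
    for i in order:
        for (chain, resseq), v in screen.results[i].per_residue.items():
            if chain == peptide_chain:
                acc.setdefault(resseq, []).append(v)
    return {pos: float(np.mean(vals)) for pos, vals in sorted(acc.items())}


# --- rotamer clash scan --------------------------------------------------


@dataclasses.dataclass
class ClashReport:
    chis: tuple[float, ...]
    clashes: list[tuple[str, int, str, str, float, float]]
    # (chain, resseq, resname, atom, distance, overlap)
    strain: float  # total vdW overlap, A


def rotamer_clash_scan(tc: TemplateComplex, chain_id: str, position: int,
                       new_restype: str,
                       tolerance: float = 0.4) -> list[ClashReport]:
    """Place every library rotamer of ``new_restype`` at (chain, resseq
    ``position``) and report vdW overlaps with all other residues.

    Returns one report per rotamer, ordered as in the library; the
    minimum-strain rotamer is the one with the smallest total overlap
    (ties to the first). A clash is any pair at distance <
    r_vdw_i + r_vdw_j - tolerance.
    """
    chain = tc.structure.chain(chain_id)
    res = chain.residue(position)
    if res is None:
        raise ValueError(f"no residue {position} in chain {chain_id}")
    if not _has_backbone(res):
        raise ValueError("scan target lacks a complete backbone")
    backbone = {n: res.atom(n).coord for n in ("N", "CA", "C")}
    others = []
    for c in tc.structure.chains:
        for r in c.residues:
            if c.id == chain_id and r.key == res.key:
                continue
            for a in r.atoms:
                el = a.element if a.element in VDW_RADII else "C"
                others.append((c.id, r.resseq, r.name, a.name, a.coord,
                               VDW_RADII[el]))
    other_coords = np.array([o[4] for o in others])
    other_radii = np.array([o[5] for o in others])
    from neomhc.chemdata import atom_element
    reports = []
    for chis, _prob in ROTAMER_LIBRARY[new_restype]:
        sc = build_sidechain(backbone, new_restype, chis)
        clashes = []
        strain = 0.0
        for name, coord in sc.items():
            el = atom_element(name)
            r_self = VDW_RADII.get(el, VDW_RADII["C"])
            d = np.linalg.norm(other_coords - coord, axis=1)
            limit = r_self + other_radii - tolerance
            for j in np.nonzero(d < limit)[0]:
                overlap = float(r_self + other_radii[j] - d[j])
                clashes.append((others[j][0], others[j][1], others[j][2],
                                others[j][3], float(d[j]), overlap))
                strain += overlap
        reports.append(ClashReport(chis=chis, clashes=clashes, strain=strain))
    return reports


def min_strain_rotamer(reports: list[ClashReport]) -> ClashReport:
    best = reports[0]
    for r in reports[1:]:
        if r.strain < best.strain:
            best = r
    return best
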