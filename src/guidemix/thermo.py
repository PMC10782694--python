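"""Thermodynamic guide features: minimum free energies of the guide:target
DNA hybrid, the 8-nt seed hybrid, the guide homodimer, and the guide
monomer fold.

The energy model is injectable so the rest of the pipeline never depends on
a compiled folding engine:

* :class:`ViennaEngine` — ViennaRNA (python bindings) for RNA folding and
  RNA:RNA duplexes;
* :class:`NearestNeighborEngine` — a self-contained nearest-neighbor model
  (Xia 1998 Watson-Crick RNA stacks; crude stem-scan approximations for
  monomer and homodimer structure);
* :class:`ConstantEngine` — a fixed-value stub for tests.

RNA:DNA hybrid energies use the Sugimoto 1995 RNA/DNA nearest-neighbor
parameters in every backend, evaluated on the perfect-complement on-target
duplex. Because the seed duplex is a sub-duplex of the full 20-nt hybrid
and all stacking terms are stabilizing, the seed energy is never below the
full-hybrid energy by construction.

All energies are kcal/mol at 37 degC, clipped at 0 (no stable structure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol

from ._util import check_dna, rna

logger = logging.getLogger(__name__)

# Sugimoto et al. 1995 RNA/DNA hybrid nearest-neighbor free energies
# (kcal/mol, 37 degC), keyed by the RNA dinucleotide 5'->3'; the DNA strand
# is the Watson-Crick complement.
SUGIMOTO_RNA_DNA: dict[str, float] = {
    "AA": -1.0, "AC": -2.1, "AG": -1.8, "AU": -0.9,
    "CA": -0.9, "CC": -2.1, "CG": -1.7, "CU": -0.9,
    "GA": -1.3, "GC": -2.7, "GG": -2.9, "GU": -1.1,
    "UA": -0.6, "UC": -1.5, "UG": -1.6, "UU": -0.2,
}
SUGIMOTO_INIT = 3.1

# Xia et al. 1998 Watson-Crick RNA/RNA stacks, keyed by the top-strand
# dinucleotide; symmetric entries filled in from the canonical ten.
_XIA_CANONICAL = {
    "AA": -0.93, "AU": -1.10, "UA": -1.33, "CU": -2.08, "CA": -2.11,
    "GU": -2.24, "GA": -2.35, "CG": -2.36, "GG": -3.26, "GC": -3.42,
}
_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _rna_revcomp(s: str) -> str:
    return "".join(_RNA_COMP[c] for c in reversed(s))


XIA_RNA_RNA: dict[str, float] = {}
for _k, _v in _XIA_CANONICAL.items():
    XIA_RNA_RNA[_k] = _v
    XIA_RNA_RNA.setdefault(_rna_revcomp(_k), _v)
XIA_INIT = 4.09


@dataclass(frozen=True)
class ThermoFeatures:
    """The four MFE features (kcal/mol, <= 0)."""

    mfe_hybrid: float
    mfe_seed_hybrid: float
    mfe_homodimer: float
    mfe_monomer: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not (v == v and abs(v) < float("inf")):
                raise ValueError(f"{name} is not finite")

    def as_dict(self) -> dict[str, float]:
        return {
            "mfe_hybrid": self.mfe_hybrid,
            "mfe_seed_hybrid": self.mfe_seed_hybrid,
            "mfe_homodimer": self.mfe_homodimer,
            "mfe_monomer": self.mfe_monomer,
        }


class ThermoEngine(Protocol):
    def monomer_mfe(self, rna_seq: str) -> float: ...

    def homoduplex_mfe(self, rna_seq: str) -> float: ...

    def hybrid_mfe(self, rna_seq: str) -> float: ...


def rna_dna_duplex_energy(rna_seq: str) -> float:
    """Nearest-neighbor energy of a perfect RNA:DNA duplex (<= 0 clip)."""
    s = rna(rna_seq)
    if len(s) < 2:
        return 0.0
    dg = SUGIMOTO_INIT + sum(
        SUGIMOTO_RNA_DNA[s[i : i + 2]] for i in range(len(s) - 1)
    )
    return min(0.0, dg)


class ConstantEngine:
    """Stub engine returning a fixed value for every query (tests)."""

    def __init__(self, value: float = -1.0):
        self.value = value

    def monomer_mfe(self, rna_seq: str) -> float:
        return self.value

    def homoduplex_mfe(self, rna_seq: str) -> float:
        return self.value

    def hybrid_mfe(self, rna_seq: str) -> float:
        return self.value


class NearestNeighborEngine:
    """Table-driven fallback with no compiled dependency.

    The hybrid is exact nearest-neighbor for a perfect duplex. Homodimer
    and monomer energies come from a best-contiguous-stem scan: every
    gapless antiparallel alignment of the sequence against itself is
    scored with the Xia stacks over its longest fully Watson-Crick run
    (plus duplex initiation; for the monomer a hairpin-loop constraint of
    >= 3 unpaired bases applies). Crude relative to a full folding engine,
    but monotone in duplex stability and exactly 0 when no Watson-Crick
    self-pairing exists (e.g. poly-A).
    """

    def hybrid_mfe(self, rna_seq: str) -> float:
        return rna_dna_duplex_energy(rna_seq)

    def _best_stem(self, a: str, b: str, min_gap: int | None) -> float:
        # Antiparallel pairing of a[i] with b[j], scanning all diagonals.
        n, m = len(a), len(b)
        best = 0.0
        for i0 in range(n):
            for j0 in range(m - 1, -1, -1):
                i, j = i0, j0
                run_start = None
                while i < n and j >= 0:
                    paired = _RNA_COMP.get(a[i]) == b[j]
                    if paired and min_gap is not None and (j - i) <= min_gap:
                        paired = False
                    if paired:
                        if run_start is None:
                            run_start = i
                    if (not paired or i == n - 1 or j == 0) and run_start is not None:
                        end = i if paired else i - 1
                        if end > run_start:
                            dg = XIA_INIT + sum(
                                XIA_RNA_RNA.get(a[k : k + 2], 0.0)
                                for k in range(run_start, end)
                            )
                            best = min(best, dg)
                        run_start = None
                    i += 1
                    j -= 1
        return best

    def homoduplex_mfe(self, rna_seq: str) -> float:
        s = rna(rna_seq)
        return min(0.0, self._best_stem(s, s, min_gap=None))

    def monomer_mfe(self, rna_seq: str) -> float:
        s = rna(rna_seq)
        return min(0.0, self._best_stem(s, s, min_gap=3))


class ViennaEngine:
    """ViennaRNA backend (RNAfold / RNAduplex equivalents via bindings)."""

    def __init__(self) -> None:
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover - env without bindings
            raise ImportError(
                "ViennaRNA python bindings are not available; use "
                "NearestNeighborEngine() or ConstantEngine() instead"
            ) from exc
        import RNA as _RNA

        self._RNA = _RNA

    def monomer_mfe(self, rna_seq: str) -> float:
        _, mfe = self._RNA.fold(rna(rna_seq))
        return min(0.0, float(mfe))

    def homoduplex_mfe(self, rna_seq: str) -> float:
        s = rna(rna_seq)
        duplex = self._RNA.duplexfold(s, s)
        return min(0.0, float(duplex.energy))

    def hybrid_mfe(self, rna_seq: str) -> float:
        return rna_dna_duplex_energy(rna_seq)


def default_engine() -> ThermoEngine:
    """ViennaRNA when importable, otherwise the nearest-neighbor table."""
    try:
        return ViennaEngine()
    except ImportError:
        logger.warning("ViennaRNA not available; using nearest-neighbor engine")
        return NearestNeighborEngine()


def thermo_features(spacer: str, context30: str, engine: ThermoEngine) -> ThermoFeatures:
    """Compute the four MFE features for one guide.

    The seed is the 8-nt PAM-proximal region of the spacer (positions
    G13..G20). Deterministic for a given engine.
    """
    s = check_dna(spacer, "spacer")
    if len(s) != 20:
        raise ValueError("spacer must be 20 nt")
    seed = s[12:20]
    return ThermoFeatures(
        mfe_hybrid=float(engine.hybrid_mfe(s)),
        mfe_seed_hybrid=float(engine.hybrid_mfe(seed)),
        mfe_homodimer=float(engine.homoduplex_mfe(s)),
        mfe_monomer=float(engine.monomer_mfe(s)),
    )
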