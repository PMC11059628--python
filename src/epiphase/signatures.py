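"""Run-length signatures and methylation footprints on single molecules.

A *footprint* is a defined set or run of consecutive cytosines on an
individual molecule held in a given state -- typically consecutive protection
against methylation flanking a cis-regulatory element.  "Consecutive" always
means adjacent in the context subsequence taken in site order (the same
convention as the consecutive-CHH quality filter), not genomic adjacency.

Two spec kinds are supported:

* ``set`` -- an explicit ordered set of context-subsequence indices that must
  all carry the spec state (e.g. "the first 2 CG sites both unmethylated");
* ``run`` -- at least ``min_run`` consecutive sites in the spec state within
  each of one or more index windows (e.g. "at least 6 consecutively methylated
  CG sites", or a run in *both* areas flanking an element -- multiple windows
  are a conjunction).

Prevalences are fractions of filtered, full-length reads matching a spec,
pooled or per biological replicate; per-replicate fractions feed the one-way
ANOVA + Tukey HSD layer for cross-condition comparison, and conditional mPPM
contrasts (footprint-bearing reads vs all reads) use the Kruskal-Wallis test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calls import MISSING, MoleculeCall
from .targets import CONTEXTS, CytosineSite
from . import stats as _stats

log = logging.getLogger(__name__)

#: Run-state label for missing calls.
MISSING_STATE = "missing"


@dataclass
class FootprintSpec:
    """Declarative single-molecule signature.

    ``site_indices`` (kind="set") and ``windows`` (kind="run") are indices
    into the target's *context subsequence* (0-based; windows half-open).
    ``state`` is 1 for methylated, 0 for unmethylated (protected).
    """

    spec_id: str
    target_id: str
    context: str
    kind: str  # "set" | "run"
    state: int
    site_indices: tuple[int, ...] = ()
    windows: tuple[tuple[int, int], ...] = ()
    min_run: int = 1

    def validate(self, sites: Sequence[CytosineSite]) -> None:
        """Fatal check that all indices lie within the context subsequence."""
        n = sum(1 for s in sites if s.context == self.context)
        if self.kind == "set":
            if not self.site_indices:
                raise ValueError(f"{self.spec_id}: set spec with no site_indices")
            if min(self.site_indices) < 0 or max(self.site_indices) >= n:
                raise ValueError(
                    f"{self.spec_id}: site_indices out of range for "
                    f"{n} {self.context} sites"
                )
        elif self.kind == "run":
            if not self.windows:
                raise ValueError(f"{self.spec_id}: run spec with no windows")
            for lo, hi in self.windows:
                if lo < 0 or hi > n or lo >= hi:
                    raise ValueError(
                        f"{self.spec_id}: window ({lo}, {hi}) out of range for "
                        f"{n} {self.context} sites"
                    )
            if self.min_run < 1:
                raise ValueError(f"{self.spec_id}: min_run must be >= 1")
        else:
            raise ValueError(f"{self.spec_id}: unknown spec kind {self.kind!r}")


@dataclass
class PrevalenceResult:
    """Fraction of reads matching a footprint spec."""

    spec_id: str
    sample: str
    replicate: str  # "" = replicates pooled
    n_reads: int
    n_matching: int

    @property
    def fraction(self) -> float:
        if self.n_reads == 0:
            return float("nan")
        return self.n_matching / self.n_reads


def runs_vector(values: np.ndarray) -> list[tuple[str, int, int]]:
    """Maximal runs of a ternary vector as ``(state, start, length)``.

    States are "1", "0" and "missing"; missing is its own state and therefore
    breaks methylated/unmethylated runs.
    """
    out: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            v = values[start]
            state = MISSING_STATE if v == MISSING else str(int(v))
            out.append((state, start, i - start))
            start = i
    return out


def runs(
    call: MoleculeCall, sites: Sequence[CytosineSite], context: str
) -> list[tuple[str, int, int]]:
    """Maximal runs over the context subsequence of one read, in site order."""
    return runs_vector(call.context_calls(sites, context))


def _has_run(values: np.ndarray, state: int, min_run: int) -> bool:
    run = 0
    for v in values:
        if v == state:
            run += 1
            if run >= min_run:
                return True
        else:
            run = 0
    return False


def match_footprint(
    call: MoleculeCall, sites: Sequence[CytosineSite], spec: FootprintSpec
) -> bool:
    """Whether one read carries the footprint.

    For ``set`` specs: every listed site is observed (non-missing) and in the
    spec state -- a non-full-length read can still match when all spec sites
    happen to be observed.  For ``run`` specs: every window contains a run of
    the spec state of length >= ``min_run`` (conjunction over windows).
    """
    sub = call.context_calls(sites, spec.context)
    if spec.kind == "set":
        idx = list(spec.site_indices)
        picked = sub[idx]
        return bool(((picked != MISSING) & (picked == spec.state)).all())
    return all(
        _has_run(sub[lo:hi], spec.state, spec.min_run) for lo, hi in spec.windows
    )


def prevalence(
    calls: Sequence[MoleculeCall],
    sites: Sequence[CytosineSite],
    spec: FootprintSpec,
    sample: str = "",
    replicate: str = "",
) -> PrevalenceResult:
    """Pooled prevalence of a spec among filtered, full-length reads.

    Non-full-length reads are excluded from the denominator.  Zero usable
    reads yields an NA fraction.
    """
    full = [c for c in calls if c.full_length]
    n_match = sum(1 for c in full if match_footprint(c, sites, spec))
    if not full:
        log.warning("prevalence %s: zero full-length reads", spec.spec_id)
    return PrevalenceResult(spec.spec_id, sample, replicate, len(full), n_match)


def prevalence_by_replicate(
    calls: Sequence[MoleculeCall],
    sites: Sequence[CytosineSite],
    spec: FootprintSpec,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict, pd.DataFrame | None]:
    """Per-replicate prevalences plus the cross-condition ANOVA/Tukey layer.

    Groups replicate-level fractions by condition and runs one-way ANOVA with
    post-hoc Tukey HSD on the percentages of reads carrying the signature.
    The tests are skipped (None) when any condition has < 2 replicates with
    reads.
    """
    rows = []
    conditions = sorted({c.sample for c in calls})
    groups: list[list[float]] = []
    for condition in conditions:
        fractions = []
        for replicate in sorted({c.replicate for c in calls if c.sample == condition}):
            sub = [c for c in calls if c.sample == condition and c.replicate == replicate]
            res = prevalence(sub, sites, spec, condition, replicate)
            rows.append(
                {
                    "spec_id": spec.spec_id,
                    "sample": condition,
                    "replicate": replicate,
                    "n_reads": res.n_reads,
                    "n_matching": res.n_matching,
                    "fraction": res.fraction,
                }
            )
            if res.n_reads > 0:
                fractions.append(res.fraction)
        groups.append(fractions)
    frame = pd.DataFrame(
        rows, columns=["spec_id", "sample", "replicate", "n_reads", "n_matching", "fraction"]
    )
    if len(conditions) < 2 or any(len(g) < 2 for g in groups):
        return frame, {"F": float("nan"), "p_value": float("nan")}, None
    f, p = _stats.anova_oneway(groups)
    tukey = _stats.tukey_hsd(groups, conditions)
    tukey["significant"] = tukey["p_value"] < alpha
    return frame, {"F": f, "p_value": p}, tukey


def conditional_mppm(
    calls: Sequence[MoleculeCall],
    sites: Sequence[CytosineSite],
    spec: FootprintSpec,
    context: str,
    window: tuple[int, int] | None = None,
    alpha: float = 0.05,
) -> dict:
    """mPPM of footprint-bearing reads vs all reads, with Kruskal-Wallis.

    ``window`` optionally restricts the mPPM to a half-open window of the
    ``context`` subsequence (the "footprint area").  Returns a dict with the
    two distributions and the test; NA (with a warning) when either stratum
    has fewer than 2 reads.
    """
    full = [c for c in calls if c.full_length]
    idx = [s.index for s in sites if s.context == context]
    if window is not None:
        idx = idx[window[0] : window[1]]

    def _values(group: Sequence[MoleculeCall]) -> np.ndarray:
        if not idx:
            return np.array([])
        return np.array([float((c.calls[idx] == 1).mean()) for c in group])

    matching = [c for c in full if match_footprint(c, sites, spec)]
    all_values = _values(full)
    match_values = _values(matching)
    if len(match_values) < 2 or len(all_values) < 2:
        log.warning(
            "conditional_mppm %s/%s: stratum with < 2 reads, returning NA",
            spec.spec_id,
            context,
        )
        return {
            "matching": match_values,
            "all": all_values,
            "H": float("nan"),
            "p_value": float("nan"),
            "significant": False,
        }
    h, p = _stats.kruskal_wallis(match_values, all_values)
    return {
        "matching": match_values,
        "all": all_values,
        "H": h,
        "p_value": p,
        "significant": bool(p < alpha),
    }


def load_footprint_specs(path: str | Path) -> list[FootprintSpec]:
    """Load footprint specs from TSV or YAML.

    TSV columns: ``spec_id, target_id, context, kind, state, indices,
    windows, min_run`` where ``indices`` is comma-separated and ``windows``
    is ``lo-hi`` pairs separated by ``;``.  A YAML file holds a list of
    mappings with the same keys.
    """
    path = Path(path)
    specs: list[FootprintSpec] = []
    if path.suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as handle:
            entries = yaml.safe_load(handle) or []
        for e in entries:
            specs.append(
                FootprintSpec(
                    spec_id=str(e["spec_id"]),
                    target_id=str(e["target_id"]),
                    context=str(e["context"]),
                    kind=str(e["kind"]),
                    state=int(e["state"]),
                    site_indices=tuple(e.get("indices", ()) or ()),
                    windows=tuple(tuple(w) for w in (e.get("windows", ()) or ())),
                    min_run=int(e.get("min_run", 1)),
                )
            )
        return specs
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in handle:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")

            def _get(name: str, default: str = "") -> str:
                i = col.get(name)
                return f[i] if i is not None and i < len(f) else default

            indices_text = _get("indices", ".").strip()
            indices = (
                tuple(int(x) for x in indices_text.split(",") if x not in ("", "."))
                if indices_text not in ("", ".")
                else ()
            )
            windows_text = _get("windows", ".").strip()
            windows = []
            if windows_text not in ("", "."):
                for chunk in windows_text.split(";"):
                    lo, _, hi = chunk.partition("-")
                    windows.append((int(lo), int(hi)))
            specs.append(
                FootprintSpec(
                    spec_id=_get("spec_id"),
                    target_id=_get("target_id"),
                    context=_get("context"),
                    kind=_get("kind"),
                    state=int(_get("state", "0")),
                    site_indices=indices,
                    windows=tuple(windows),
                    min_run=int(_get("min_run", "1") or 1),
                )
            )
    return specs
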