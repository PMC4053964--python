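"""Truth-based evaluation of pipeline output on synthetic studies.

Maps called crosslinking sites back to the generator's planted sites
(maximal-overlap matching) and scores boundary recovery, FDR-threshold
sensitivity, and differential-call accuracy against planted truth.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .synthetic_data import PlantedSite, TruthSet


def best_match(planted: PlantedSite, sites: Iterable):
    """The called site with maximal overlap with a planted site, or None."""
    best, best_ov = None, 0
    for s in sites:
        ov = s.interval.overlap(planted.interval)
        if ov > best_ov:
            best, best_ov = s, ov
    return best


def boundary_error(planted: PlantedSite, site) -> int:
    """Max per-side distance between called and planted boundaries."""
    return max(
        abs(site.interval.start - planted.interval.start),
        abs(site.interval.end - planted.interval.end),
    )


def site_recovery(truth: TruthSet, sites, max_boundary_error: int = 5) -> dict:
    """Fraction of planted sites recovered within a boundary tolerance.

    ``sites`` should already be filtered (e.g. FDR < 0.01). Also reports
    the mean length of the called sites for comparison with the planted
    site-length distribution.
    """
    errors = []
    recovered = 0
    for p in truth.sites:
        m = best_match(p, sites)
        if m is None:
            errors.append(None)
            continue
        e = boundary_error(p, m)
        errors.append(e)
        if e <= max_boundary_error:
            recovered += 1
    lengths = [len(s.interval) for s in sites]
    return {
        "n_planted": len(truth.sites),
        "n_recovered": recovered,
        "recovery_rate": recovered / len(truth.sites) if truth.sites else 0.0,
        "boundary_errors": errors,
        "mean_called_length": float(np.mean(lengths)) if lengths else np.nan,
    }


def truth_class(planted: PlantedSite, condition: str) -> str:
    f = planted.fold[condition]
    return "increased" if f > 1 else ("decreased" if f < 1 else "unchanged")


def representative_calls(truth: TruthSet, sites, calls) -> dict:
    """planted site_id -> DifferentialCall of its representative called site.

    The representative is the maximal-overlap called site; ``calls`` must be
    parallel to ``sites``.
    """
    out = {}
    site_to_call = {id(s): c for s, c in zip(sites, calls)}
    for p in truth.sites:
        m = best_match(p, sites)
        if m is not None:
            out[p.site_id] = site_to_call[id(m)]
    return out


def differential_accuracy(truth: TruthSet, sites, calls,
                          condition: str) -> dict:
    """Sensitivity on planted changes and false-call rate on planted
    unchanged sites, judging each planted site by its representative call."""
    rep = representative_calls(truth, sites, calls)
    tp = fn = fp = n_changed = n_unchanged = 0
    for p in truth.sites:
        c = rep.get(p.site_id)
        if c is None or c.call == "excluded_low_coverage":
            continue
        t = truth_class(p, condition)
        if t == "unchanged":
            n_unchanged += 1
            if c.call in ("increased", "decreased"):
                fp += 1
        else:
            n_changed += 1
            if c.call == t:
                tp += 1
            else:
                fn += 1
    return {
        "n_changed": n_changed,
        "n_unchanged": n_unchanged,
        "sensitivity": tp / n_changed if n_changed else np.nan,
        "false_call_rate": fp / n_unchanged if n_unchanged else np.nan,
    }


def _venn(set1: set, set2: set) -> tuple:
    return (len(set1 - set2), len(set2 - set1), len(set1 & set2))


def truth_venn(truth: TruthSet, cond_1: str, cond_2: str,
               universe_1: Iterable[str] | None = None,
               universe_2: Iterable[str] | None = None) -> dict:
    """Planted Venn counts per class between two stress conditions.

    ``universe_1``/``universe_2`` restrict each comparison to the planted
    sites analyzable in it (e.g. not excluded for low coverage there).
    """
    all_ids = {p.site_id for p in truth.sites}
    u1 = set(universe_1) if universe_1 is not None else all_ids
    u2 = set(universe_2) if universe_2 is not None else all_ids
    out = {}
    for klass in ("increased", "decreased"):
        s1 = {p.site_id for p in truth.sites
              if p.site_id in u1 and truth_class(p, cond_1) == klass}
        s2 = {p.site_id for p in truth.sites
              if p.site_id in u2 and truth_class(p, cond_2) == klass}
        out[klass] = _venn(s1, s2)
    return out


def analyzable_ids(truth: TruthSet, sites, calls) -> set:
    """Planted sites whose representative call is not coverage-excluded."""
    rep = representative_calls(truth, sites, calls)
    return {pid for pid, c in rep.items()
            if c.call != "excluded_low_coverage"}


def called_venn(truth: TruthSet, sites, calls_1, calls_2) -> dict:
    """Venn counts over planted sites judged by their representative calls."""
    rep1 = representative_calls(truth, sites, calls_1)
    rep2 = representative_calls(truth, sites, calls_2)
    out = {}
    for klass in ("increased", "decreased"):
        s1 = {pid for pid, c in rep1.items() if c.call == klass}
        s2 = {pid for pid, c in rep2.items() if c.call == klass}
        out[klass] = _venn(s1, s2)
    return out
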