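"""Independent brute-force oracles for the time-course statistics.

Deliberately naive: for every compound and every year the target set is
rebuilt from scratch by scanning all records, with no shared code or
vectorization, so these can serve as an independent cross-check of the
library implementations on small datasets.
"""

from __future__ import annotations


def records_as_tuples(dataset):
    """(compound_id, target_id, assay_id, release_year) per record."""
    out = []
    for r in dataset.records():
        out.append((r.compound_id, r.target_id, r.assay_id, r.release_year))
    return out


def brute_promiscuity(dataset, horizon=None):
    """Per compound: (first_year, {year: cumulative distinct-target count})."""
    recs = records_as_tuples(dataset)
    assert all(y is not None for _, _, _, y in recs)
    if horizon is None:
        horizon = max(y for _, _, _, y in recs)
    compounds = sorted({c for c, _, _, _ in recs})
    result = {}
    for cid in compounds:
        own = [(t, y) for c, t, _, y in recs if c == cid]
        first = min(y for _, y in own)
        degrees = {}
        for year in range(first, horizon + 1):
            targets = set()
            for t, y in own:
                if y <= year:
                    targets.add(t)
            degrees[year] = len(targets)
        result[cid] = (first, degrees)
    return result


def brute_annual_mean(dataset, horizon=None):
    """{year: mean degree over compounds first seen by that year}."""
    prom = brute_promiscuity(dataset, horizon)
    years = set()
    for _, degrees in prom.values():
        years.update(degrees)
    out = {}
    for year in sorted(years):
        degs = [degrees[year] for first, degrees in prom.values() if first <= year]
        if degs:
            out[year] = sum(degs) / len(degs)
    return out


def brute_delta_bin(delta):
    if delta < 0:
        raise ValueError(delta)
    if delta <= 5:
        return str(delta)
    if delta <= 10:
        return "6–10"
    if delta <= 20:
        return "11–20"
    if delta <= 50:
        return "21–50"
    return ">50"


def brute_delta_histogram(dataset, horizon=None):
    """{bin label: compound count} over the promiscuity gains."""
    prom = brute_promiscuity(dataset, horizon)
    counts = {}
    for first, degrees in prom.values():
        final_year = max(degrees)
        delta = degrees[final_year] - degrees[first]
        label = brute_delta_bin(delta)
        counts[label] = counts.get(label, 0) + 1
    return counts


def brute_growth(dataset, kind):
    """{year: n_new} for one entity kind, earliest-appearance semantics."""
    recs = records_as_tuples(dataset)
    column = {"compounds": 0, "targets": 1, "assays": 2}
    new_counts = {}
    if kind == "activities":
        for _, _, _, y in recs:
            new_counts[y] = new_counts.get(y, 0) + 1
    else:
        idx = column[kind]
        entities = {r[idx] for r in recs}
        for ent in entities:
            first = min(y for r in recs if r[idx] == ent for y in [r[3]])
            new_counts[first] = new_counts.get(first, 0) + 1
    return new_counts
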