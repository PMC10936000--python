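#!/usr/bin/env python
"""ISM hierarchy of the seven significant drill-effectiveness factors.

Takes the expert-elicited direct-influence matrix over the seven factors
(S1 training frequency, S2 training quality, S3 fund guarantee, S4 equipment
and facilities, S5 leaders' focus, S6 inter-departmental coordination,
S7 plan-designing skill), computes the Boolean reachability closure, the
per-factor reachable/antecedent/common sets, the level partition, and the
transitively reduced hierarchy digraph.  Writes the factor-set table and the
DOT rendering to results/.
"""

import argparse
import json
from pathlib import Path

from logistic_ism import datasets
from logistic_ism.ism import (
    FactorSystem,
    build_hierarchy,
    export_graph,
    factor_sets,
    partition_levels,
    reachability_closure,
    validate_adjacency,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--adjacency", type=Path, help="optional 0/1 adjacency CSV (header = labels)"
    )
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    if args.adjacency:
        from logistic_ism.ism import load_adjacency_csv

        labels, entries = load_adjacency_csv(args.adjacency)
        names = None
    else:
        labels, entries = datasets.expert_adjacency()
        names = dict(datasets.FACTOR_NAMES)

    R = validate_adjacency(entries)
    M = reachability_closure(R)
    fs = factor_sets(M, labels)
    partition = partition_levels(M, labels)

    print(f"{'Factor':<8}{'R(Si)':<30}{'T(Si)':<30}")
    for lab in labels:
        print(
            f"{lab:<8}{', '.join(sorted(fs.reachable[lab])):<30}"
            f"{', '.join(sorted(fs.common[lab])):<30}"
        )
    print()
    tags = {1: "surface", partition.n_levels: "bottom"}
    for i, level in enumerate(partition.levels, start=1):
        tag = tags.get(i, "middle")
        members = ", ".join(
            f"{lab} ({names[lab]})" if names else lab for lab in sorted(level)
        )
        print(f"Level {i} ({tag}): {members}")

    system = FactorSystem(labels=tuple(labels), names=names)
    graph = build_hierarchy(R, partition, system)
    (args.out / "hierarchy.dot").write_text(export_graph(graph))
    (args.out / "factor_sets.json").write_text(
        json.dumps(
            {
                lab: {
                    "reachable": sorted(fs.reachable[lab]),
                    "antecedent": sorted(fs.antecedent[lab]),
                    "common": sorted(fs.common[lab]),
                }
                for lab in labels
            },
            indent=2,
        )
    )
    print(f"\nretained influence links: {len(graph.edges)}")
    print(f"wrote {args.out / 'hierarchy.dot'} and {args.out / 'factor_sets.json'}")


if __name__ == "__main__":
    main()
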