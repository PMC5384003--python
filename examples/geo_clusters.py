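"""Cluster participants into one-degree map cells by their reported zip codes.

Zips are normalized (5 digits, zero-padded, ZIP+4 suffix dropped), looked up
in a gazetteer, and each participant lands in the cell
(floor(latitude), ceiling(longitude)).  Each cell reports its member count,
median P-index and a plot point at the median unrounded coordinates —
everything needed to draw the usual hotspot map with any plotting tool.
"""

from pindex import (SimParams, cluster_geopoints, default_survey_catalog,
                    generate_cohort, generate_gazetteer, geocode_participants,
                    run_pipeline)

params = SimParams(n_participants=800, seed=5)
sim = generate_cohort(params)
result = run_pipeline(sim.cohort(), default_survey_catalog(params))

gazetteer = generate_gazetteer(params)
points = geocode_participants(result.cohort, gazetteer)
print(f"geocoded {len(points)} participants "
      f"({points.attrs['n_unmatched']} zips unmatched)")

clusters = cluster_geopoints(points, result.ptable)
print(f"{len(clusters)} one-degree cells; five largest:")
top = clusters.sort_values("n", ascending=False).head(5)
print(top.drop(columns="member_ids").to_string(index=False))
# cell_lat/cell_lon is the grid key; plot_lat/plot_lon is where a map marker
# for the cell would be drawn, sized by n and colored by median_p_index.
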