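"""Load the packaged 47-compound Freundlich parameter table and summarize it.

K (in (mg/g)(L/mg)^(1/n)) measures adsorption capacity on activated
carbon; 1/n measures isotherm nonlinearity.  The printed extremes show
how widely adsorption behaviour varies across common organic water
contaminants.
"""

from freundlich_qsar import load_freundlich_table

table = load_freundlich_table()
k = table.df["K"]
n = table.df["one_over_n"]

print(f"compounds:            {len(table)}")
print(f"mean K:               {k.mean():.0f}")
print(f"mean 1/n:             {n.mean():.3f}")
imin, imax = n.idxmin(), n.idxmax()
print(f"smallest 1/n:         {n[imin]:.3f} ({table.df['name'][imin]}, K={k[imin]:.0f})")
print(f"largest 1/n:          {n[imax]:.3f} ({table.df['name'][imax]}, K={k[imax]:.0f})")
print(f"spread of 1/n:        {n.max() - n.min():.3f}")

# A small 1/n with a large K (glyphosate) marks strong, highly
# heterogeneous adsorption; the opposite corner (oxamyl) adsorbs weakly
# but almost linearly.
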