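"""Walk the frequency ladder and print its distribution summaries.

Starting from the bundled table (major haplotype at 0.552), each ladder
step moves 0.05 off the major haplotype and adds 0.005 to each of the ten
originally rarest haplotypes.  The printout shows, per step, the standard
deviation of the 17 frequencies and the shares of mass carried by the 10
identified references and by the two entries that the "incorrect
reference" construction corrupts.
"""

from kirphase import builtin_table1, identified_references, modify_distribution
from kirphase.simulator import distribution_summary, make_incorrect_references

_, table = builtin_table1()
refs = identified_references(table, 10)
corrupted = make_incorrect_references(refs)
print("corrupted reference 1:", corrupted[0])
print("step  top-freq  sd     identified%  corrupted-source%")
for step in range(10):
    freqs = modify_distribution(table, step)
    s = distribution_summary(freqs, refs, replaced=refs[:2])
    top = max(freqs.values())
    print(f"{step:>4}  {top:.3f}     {s.sd:.3f}  {s.identified_pct:>10}  {s.incorrect_pct:>17}")
# The flatter the distribution (small sd), the less the identified
# references cover the sample and the harder phasing becomes.
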