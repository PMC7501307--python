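# aaopt

Minimal binary-feature classifications of the 20 proteinogenic amino acids.

## The problem

Classical amino-acid classification schemes (Taylor-style Euler diagrams
built from adjectives like *small*, *polar*, *hydrophobic*) are easy to
interpret but redundant: they use more features than necessary and still
leave some residues indistinguishable. Information-theoretically, five
binary features suffice, because 2⁵ = 32 ≥ 20, while four (2⁴ = 16) do
not. `aaopt` searches numeric feature tables — typically indices from the
AAindex1 database, such as volume, hydrophobicity, electron–ion
interaction potential, or helix propensities — for *every* set of five
features whose repeated binary separation assigns each residue a unique
5-bit code. Such a solution defines a biochemical niche per residue,
leaves exactly 32 − 20 = 12 codes empty, and those empty codes are
candidate niches for non-canonical amino acids in genetic-code
expansion.

## The method

For a feature with values *x₁ … x₂₀*:

- the **median separation** puts residues with *x ≤ median* in the low
  set and the rest in the high set (a 10/10 split when values are
  distinct);
- more generally, every **realizable cut** between two strictly
  different adjacent sorted values is a candidate separation; its
  **gap** is the value difference across the cut, and its **score** is
  the number of other cuts of the same feature with a strictly smaller
  gap (0–18 for 20 distinct values), so high scores mark natural
  separation points. A solution's **cumulative score** is the sum over
  its five separations (max 5 × 18 = 90).

The search refines a partition of the residue set one separation at a
time and prunes with the **capacity (non-redundancy) criterion**: after
*n* of *f* features, no cell may hold more than 2^(f−n) residues, or the
remaining features cannot isolate its members. Cuts whose sides exceed
2^(f−1) (outside [4, 16] for 20 residues) are excluded up front. A
depth-*f* partition with at most one residue per cell is a solution;
solutions are unordered feature sets, each admitting 5! = 120 equivalent
tree layouts.

Downstream analyses: leave-one-residue-out **redundancy profiling** (how
many extra solutions appear when one residue is dropped before the
search), **empty-niche assessment** (how often a candidate amino acid's
code lands on an unoccupied vector across solutions), group
**adjective labelling**, and an identical-separation check for screening
correlated substitute features.

## Worked example

The synthetic generator plants a known five-feature classification
(`PLANT01`–`PLANT05`, values in two bands separated by a dominant gap)
plus noise features that no valid cut can use:

```sh
aaopt simulate --seed 7 --n-noise 3 --out table.tsv --design design.json
aaopt search table.tsv --mode cuts --top-cuts 3 --out solutions.json
aaopt score solutions.json
```

which prints

```
solutions	2
top_cumulative_score	90
```

Two feature sets classify all 20 residues uniquely; the top one is the
planted set with the maximal cumulative score 90 (five separations each
at their feature's widest gap, rank 18 of 19 cuts). Inspecting
`solutions.json`, the top solution uses `PLANT01 … PLANT05`, leaves 12
of the 32 codes empty, and assigns e.g. glycine the code `10011` —
meaning G is on the high side of features 1, 4 and 5 and the low side of
features 2 and 3. Exports:

```sh
aaopt export solutions.json --what dot --out tree.dot     # binary tree, 32 leaves
aaopt export solutions.json --what euler --side high      # per-feature residue sets
aaopt redundancy table.tsv --mode cuts --top-cuts 1       # leave-one-out profile
```

On this planted table the redundancy profile reports
`additional_solutions = 0` for every residue: the single planted
solution survives every deletion and no new ones appear.

Real data works the same way: parse an AAindex1 flat file with
`aaopt parse`, curate it to a hand-picked accession list with
`--features my_accessions.txt` (one accession per line, `#` comments),
and run `aaopt search --mode median` or `--mode cuts --top-cuts 3`. The
repository deliberately ships no copy of AAindex; place a flat file at
`data/aaindex1.txt` and a curated list at `data/curated_accessions.txt`
to activate the database-level reproduction test.

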