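# Curated enzyme-free biotransformation rules, one reaction SMARTS each,
# bucketed into the eight functional-group categories used by the ranker.
# Schema: rule_id, name, category, reaction_smarts, notes.
- rule_id: E01
  name: ester hydrolysis
  category: esters
  reaction_smarts: "[CX3:1](=[OX1:2])[OX2:3][#6:4]>>[C:1](=[O:2])[OH:3].[#6:4][OH]"
  notes: >
    Covers acyl esters, lactones (ring opening) and glycosyl esters such as
    glucuronide esters; gastric/intestinal and esterase-independent hydrolysis.
- rule_id: T01
  name: ether cleavage
  category: ethers
  reaction_smarts: "[#6;!$([CX3]=[OX1]):1][OX2:2][#6;!$([CX3]=[OX1]):3]>>[#6:1][OH:2].[#6:3][OH]"
  notes: >
    O-dealkylation and glycosidic C-O-C cleavage (deglycosylation of O-glycosides
    by gut microbiota); the ester bridging oxygen is masked out.
- rule_id: A01
  name: aromatic hydroxylation
  category: aromatics
  reaction_smarts: "[cH:1]>>[c:1]O"
  notes: arene oxidation to phenol at any unsubstituted aromatic CH.
- rule_id: K01
  name: alkene reduction
  category: alkenes
  reaction_smarts: "[CX3;!$([CX3]=[OX1]):1]=[CX3:2]>>[C:1][C:2]"
  notes: saturation of a non-aromatic C=C double bond.
- rule_id: K02
  name: alkene hydration
  category: alkenes
  reaction_smarts: "[CX3;!$([CX3]=[OX1]):1]=[CX3:2]>>[C:1][C:2]O"
  notes: Markovnikov and anti-Markovnikov products both enumerated.
- rule_id: L01
  name: primary alcohol oxidation
  category: alcohols
  reaction_smarts: "[CX4;H2:1][OX2H:2]>>[C:1](=[O:2])O"
  notes: primary alcohol to carboxylic acid (via the aldehyde, collapsed).
- rule_id: L02
  name: secondary alcohol oxidation
  category: alcohols
  reaction_smarts: "[CX4;H1:1]([#6:3])([#6:4])[OX2H:2]>>[C:1](=[O:2])([#6:3])[#6:4]"
  notes: secondary alcohol to ketone.
- rule_id: L03
  name: hydroxyl glucuronidation
  category: alcohols
  reaction_smarts: "[OX2H:1][#6:2]>>[#6:2][O:1]C1OC(C(=O)O)C(O)C(O)C1O"
  notes: O-glucuronide conjugation of an alcoholic or phenolic hydroxyl.
- rule_id: N01
  name: methyl hydroxylation
  category: alkanes
  reaction_smarts: "[CX4;H3;$([CX4][#6]):1]>>[C:1]O"
  notes: omega-hydroxylation of a methyl attached to carbon.
- rule_id: N02
  name: methylene hydroxylation
  category: alkanes
  reaction_smarts: "[CX4;H2;$([CX4]([#6])[#6]):1]>>[C:1]O"
  notes: hydroxylation of a methylene flanked by two carbons.
- rule_id: M01
  name: N-demethylation
  category: amines
  reaction_smarts: "[NX3;!$([NX3][CX3]=[OX1]):1][CH3]>>[N:1]"
  notes: oxidative removal of an N-methyl group; amide nitrogens excluded.
- rule_id: M02
  name: N-acetylation
  category: amines
  reaction_smarts: "[NX3;H2,H1;!$([NX3][CX3]=[OX1]);$([NX3][#6]):1]>>[N:1]C(C)=O"
  notes: acetyl conjugation of a primary or secondary amine.
- rule_id: O01
  name: ketone reduction
  category: others
  reaction_smarts: "[#6:1][CX3:2](=[OX1:3])[#6:4]>>[#6:1][CH1:2]([OH:3])[#6:4]"
  notes: carbonyl reduction of a ketone to the secondary alcohol.
- rule_id: O02
  name: amide hydrolysis
  category: others
  reaction_smarts: "[CX3:1](=[OX1:2])[NX3:3]>>[C:1](=[O:2])[OH].[N:3]"
  notes: amide bond cleavage to the carboxylic acid and the amine.
- rule_id: O03
  name: decarboxylation
  category: others
  reaction_smarts: "[#6:1][CX3](=[OX1])[OX2H]>>[#6:1]"
  notes: loss of a carboxyl group as CO2.
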