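<Enzymes>
  <Enzyme>
    <Name>Arg-C proteinase</Name>
    <Pattern>R</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Cleaves after arginine.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Asp-N endopeptidase</Name>
    <Pattern>D</Pattern>
    <DistanceToCleavagePoint>0</DistanceToCleavagePoint>
    <Description>Cleaves before aspartate.</Description>
  </Enzyme>
  <Enzyme>
    <Name>BNPS-Skatole</Name>
    <Pattern>W</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Chemical cleavage after tryptophan.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Caspase 1</Name>
    <Pattern>[FWYL]EHD(?![PEDQKR])</Pattern>
    <DistanceToCleavagePoint>4</DistanceToCleavagePoint>
    <Description>Cleaves after D in the motif [FWYL]EHD unless followed by P/E/D/Q/K/R.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Caspase 2</Name>
    <Pattern>DVAD(?![PEDQKR])</Pattern>
    <DistanceToCleavagePoint>4</DistanceToCleavagePoint>
    <Description>Cleaves after D in DVAD unless followed by P/E/D/Q/K/R.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Caspase 3</Name>
    <Pattern>DMQD(?![PEDQKR])</Pattern>
    <DistanceToCleavagePoint>4</DistanceToCleavagePoint>
    <Description>Cleaves after D in DMQD unless followed by P/E/D/Q/K/R.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Caspase 4</Name>
    <Pattern>LEVD(?![PEDQKR])</Pattern>
    <DistanceToCleavagePoint>4</DistanceToCleavagePoint>
    <Description>Cleaves after D in LEVD unless followed by P/E/D/Q/K/R.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Caspase 5</Name>
    <Pattern>[LW]EHD</Pattern>
    <DistanceToCleavagePoint>4</DistanceToCleavagePoint>
    <Description>Cleaves after D in [LW]EHD.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Caspase 6</Name>
    <Pattern>VE[HI]D(?![PEDQKR])</Pattern>
    <DistanceToCleavagePoint>4</DistanceToCleavagePoint>
    <Description>Cleaves after D in VE[HI]D unless followed by P/E/D/Q/K/R.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Caspase 7</Name>
    <Pattern>DEVD(?![PEDQKR])</Pattern>
    <DistanceToCleavagePoint>4</DistanceToCleavagePoint>
    <Description>Cleaves after D in DEVD unless followed by P/E/D/Q/K/R.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Caspase 8</Name>
    <Pattern>[IL]ETD(?![PEDQKR])</Pattern>
    <DistanceToCleavagePoint>4</DistanceToCleavagePoint>
    <Description>Cleaves after D in [IL]ETD unless followed by P/E/D/Q/K/R.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Caspase 9</Name>
    <Pattern>LEHD</Pattern>
    <DistanceToCleavagePoint>4</DistanceToCleavagePoint>
    <Description>Cleaves after D in LEHD.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Caspase 10</Name>
    <Pattern>IEAD</Pattern>
    <DistanceToCleavagePoint>4</DistanceToCleavagePoint>
    <Description>Cleaves after D in IEAD.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Chymotrypsin (high specificity)</Name>
    <Pattern>(F(?!P)|Y(?!P)|W(?![MP]))</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Cleaves after F/Y (not before P) and W (not before M or P).</Description>
  </Enzyme>
  <Enzyme>
    <Name>Chymotrypsin (low specificity)</Name>
    <Pattern>(F(?!P)|L(?!P)|Y(?!P)|W(?![MP])|M(?![PY])|H(?![DMPW]))</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Cleaves after F/L/Y/W/M/H with PeptideCutter exception residues.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Clostripain</Name>
    <Pattern>R</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Clostridiopeptidase B; cleaves after arginine.</Description>
  </Enzyme>
  <Enzyme>
    <Name>CNBr</Name>
    <Pattern>M</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Cyanogen bromide; chemical cleavage after methionine.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Enterokinase</Name>
    <Pattern>[DE]{3}K</Pattern>
    <DistanceToCleavagePoint>4</DistanceToCleavagePoint>
    <Description>Cleaves after K preceded by three acidic residues.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Factor Xa</Name>
    <Pattern>[AFGILTVM][DE]GR</Pattern>
    <DistanceToCleavagePoint>4</DistanceToCleavagePoint>
    <Description>Cleaves after R in the motif [AFGILTVM][DE]GR.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Formic acid</Name>
    <Pattern>D</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Chemical cleavage after aspartate.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Glutamyl endopeptidase</Name>
    <Pattern>E</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Glu-C (bicarbonate); cleaves after glutamate.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Granzyme B</Name>
    <Pattern>IEPD</Pattern>
    <DistanceToCleavagePoint>4</DistanceToCleavagePoint>
    <Description>Cleaves after D in IEPD.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Hydroxylamine</Name>
    <Pattern>N(?=G)</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Chemical cleavage of asparagine-glycine bonds.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Iodosobenzoic acid</Name>
    <Pattern>W</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Chemical cleavage after tryptophan.</Description>
  </Enzyme>
  <Enzyme>
    <Name>LysC</Name>
    <Pattern>K</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Cleaves after lysine.</Description>
  </Enzyme>
  <Enzyme>
    <Name>NTCB</Name>
    <Pattern>C</Pattern>
    <DistanceToCleavagePoint>0</DistanceToCleavagePoint>
    <Description>2-nitro-5-thiocyanobenzoic acid; cleaves before cysteine.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Pepsin (pH 1.3)</Name>
    <Pattern>((?&lt;=[^HKR][^P])[^R](?=[FL][^P]))|((?&lt;=[^HKR][^P])[FL](?=[ACDEFGHIKLMNPQRSTVWY][^P]))</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Cleaves adjacent to F/L with PeptideCutter positional exceptions.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Pepsin (pH &gt; 2)</Name>
    <Pattern>((?&lt;=[^HKR][^P])[^R](?=[FLWY][^P]))|((?&lt;=[^HKR][^P])[FLWY](?=[ACDEFGHIKLMNPQRSTVWY][^P]))</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Cleaves adjacent to F/L/W/Y with PeptideCutter positional exceptions.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Proline endopeptidase</Name>
    <Pattern>(?&lt;=[HKR])P(?!P)</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Cleaves after P preceded by H/K/R, not before another P.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Proteinase K</Name>
    <Pattern>[AEFILTVWY]</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Broad specificity; cleaves after aliphatic and aromatic residues.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Staphylococcal peptidase I</Name>
    <Pattern>(?&lt;=[^E])E</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Cleaves after E not preceded by E.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Thermolysin</Name>
    <Pattern>[^DE](?=[AFILMV])</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Cleaves before bulky hydrophobic residues not preceded by D/E.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Thrombin</Name>
    <Pattern>((?&lt;=[AFGILTVM][AFGILTVWA]P)R(?=[^DE][^DE]))|((?&lt;=G)R(?=G))</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Cleaves after R in GR-G context or the extended hydrophobic-P-R motif.</Description>
  </Enzyme>
  <Enzyme>
    <Name>Trypsin</Name>
    <Pattern>([KR](?!P))|((?&lt;=W)K(?=P))|((?&lt;=M)R(?=P))</Pattern>
    <DistanceToCleavagePoint>1</DistanceToCleavagePoint>
    <Description>Cleaves after K/R not before P, with the WKP and MRP exception motifs.</Description>
  </Enzyme>
</Enzymes>
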