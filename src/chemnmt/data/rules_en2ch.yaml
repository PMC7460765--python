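# Demonstration rule set for the three-stage rule-based translator.
# Covers only the package's toy nomenclature grammar; it is an open
# stand-in illustrating the disassembly/translation/reassembly
# architecture, not a production rule set.
direction: En2Ch
aromatic_parents:
- benzene
ester_triggers:
- oate
- formate
- acetate
- ' ester'
builtin_locants: true
lexicon:
- text: methan
  role: parent
- text: methane
  role: parent
- text: methylamine
  role: parent
- text: methyl
  role: substituent
- text: ethan
  role: parent
- text: ethane
  role: parent
- text: ethylamine
  role: parent
- text: ethyl
  role: substituent
- text: propan
  role: parent
- text: propane
  role: parent
- text: propylamine
  role: parent
- text: propyl
  role: substituent
- text: butan
  role: parent
- text: butane
  role: parent
- text: butylamine
  role: parent
- text: butyl
  role: substituent
- text: pentan
  role: parent
- text: pentane
  role: parent
- text: pentylamine
  role: parent
- text: pentyl
  role: substituent
- text: hexan
  role: parent
- text: hexane
  role: parent
- text: hexylamine
  role: parent
- text: hexyl
  role: substituent
- text: heptan
  role: parent
- text: heptane
  role: parent
- text: heptylamine
  role: parent
- text: heptyl
  role: substituent
- text: octan
  role: parent
- text: octane
  role: parent
- text: octylamine
  role: parent
- text: octyl
  role: substituent
- text: nonan
  role: parent
- text: nonane
  role: parent
- text: nonylamine
  role: parent
- text: nonyl
  role: substituent
- text: decan
  role: parent
- text: decane
  role: parent
- text: decylamine
  role: parent
- text: decyl
  role: substituent
- text: chloro
  role: substituent
- text: bromo
  role: substituent
- text: fluoro
  role: substituent
- text: iodo
  role: substituent
- text: amine
  role: suffix
- text: benzene
  role: parent
- text: ethenyl
  role: substituent
- text: ol
  role: suffix
- text: oic acid
  role: suffix
- text: oate
  role: ester_acyl
- text: formate
  role: ester_acyl
- text: acetate
  role: ester_acyl
- text: ' ester'
  role: ester_acyl
- text: di
  role: multiplier
- text: tri
  role: multiplier
- text: '-'
  role: punctuation
- text: ', '
  role: punctuation
- text: ' '
  role: punctuation
dictionary:
- text: methan
  role: parent
  context: default
  translation: 甲
- text: methane
  role: parent
  context: default
  translation: 甲烷
- text: methylamine
  role: parent
  context: default
  translation: 甲胺
- text: methyl
  role: substituent
  context: default
  translation: 甲基
- text: methyl
  role: substituent
  context: ester
  translation: 甲
- text: ethan
  role: parent
  context: default
  translation: 乙
- text: ethane
  role: parent
  context: default
  translation: 乙烷
- text: ethylamine
  role: parent
  context: default
  translation: 乙胺
- text: ethyl
  role: substituent
  context: default
  translation: 乙基
- text: ethyl
  role: substituent
  context: ester
  translation: 乙
- text: propan
  role: parent
  context: default
  translation: 丙
- text: propane
  role: parent
  context: default
  translation: 丙烷
- text: propylamine
  role: parent
  context: default
  translation: 丙胺
- text: propyl
  role: substituent
  context: default
  translation: 丙基
- text: propyl
  role: substituent
  context: ester
  translation: 丙
- text: butan
  role: parent
  context: default
  translation: 丁
- text: butane
  role: parent
  context: default
  translation: 丁烷
- text: butylamine
  role: parent
  context: default
  translation: 丁胺
- text: butyl
  role: substituent
  context: default
  translation: 丁基
- text: butyl
  role: substituent
  context: ester
  translation: 丁
- text: pentan
  role: parent
  context: default
  translation: 戊
- text: pentane
  role: parent
  context: default
  translation: 戊烷
- text: pentylamine
  role: parent
  context: default
  translation: 戊胺
- text: pentyl
  role: substituent
  context: default
  translation: 戊基
- text: pentyl
  role: substituent
  context: ester
  translation: 戊
- text: hexan
  role: parent
  context: default
  translation: 己
- text: hexane
  role: parent
  context: default
  translation: 己烷
- text: hexylamine
  role: parent
  context: default
  translation: 己胺
- text: hexyl
  role: substituent
  context: default
  translation: 己基
- text: hexyl
  role: substituent
  context: ester
  translation: 己
- text: heptan
  role: parent
  context: default
  translation: 庚
- text: heptane
  role: parent
  context: default
  translation: 庚烷
- text: heptylamine
  role: parent
  context: default
  translation: 庚胺
- text: heptyl
  role: substituent
  context: default
  translation: 庚基
- text: heptyl
  role: substituent
  context: ester
  translation: 庚
- text: octan
  role: parent
  context: default
  translation: 辛
- text: octane
  role: parent
  context: default
  translation: 辛烷
- text: octylamine
  role: parent
  context: default
  translation: 辛胺
- text: octyl
  role: substituent
  context: default
  translation: 辛基
- text: octyl
  role: substituent
  context: ester
  translation: 辛
- text: nonan
  role: parent
  context: default
  translation: 壬
- text: nonane
  role: parent
  context: default
  translation: 壬烷
- text: nonylamine
  role: parent
  context: default
  translation: 壬胺
- text: nonyl
  role: substituent
  context: default
  translation: 壬基
- text: nonyl
  role: substituent
  context: ester
  translation: 壬
- text: decan
  role: parent
  context: default
  translation: 癸
- text: decane
  role: parent
  context: default
  translation: 癸烷
- text: decylamine
  role: parent
  context: default
  translation: 癸胺
- text: decyl
  role: substituent
  context: default
  translation: 癸基
- text: decyl
  role: substituent
  context: ester
  translation: 癸
- text: chloro
  role: substituent
  context: default
  translation: 氯
- text: bromo
  role: substituent
  context: default
  translation: 溴
- text: fluoro
  role: substituent
  context: default
  translation: 氟
- text: iodo
  role: substituent
  context: default
  translation: 碘
- text: amine
  role: suffix
  context: default
  translation: 胺
- text: benzene
  role: parent
  context: default
  translation: 苯
- text: ethenyl
  role: substituent
  context: default
  translation: 乙烯基
- text: ol
  role: suffix
  context: default
  translation: 醇
- text: ol
  role: suffix
  context: aromatic
  translation: 酚
- text: oic acid
  role: suffix
  context: default
  translation: 酸
- text: oate
  role: ester_acyl
  context: default
  translation: 酸
- text: formate
  role: ester_acyl
  context: default
  translation: 甲酸
- text: acetate
  role: ester_acyl
  context: default
  translation: 乙酸
- text: ' ester'
  role: ester_acyl
  context: default
  translation: 酯
- text: di
  role: multiplier
  context: default
  translation: 二
- text: tri
  role: multiplier
  context: default
  translation: 三
- text: '-'
  role: punctuation
  context: default
  translation: '-'
- text: ', '
  role: punctuation
  context: default
  translation: ''
- text: ' '
  role: punctuation
  context: default
  translation: ''
templates:
- match:
  - substituent
  - ester_acyl
  output:
  - 1
  - 0
  - 酯
- match:
  - substituent
  - parent
  - ester_acyl
  output:
  - 1
  - 2
  - 0
  - 酯
- match:
  - substituent
  - locant
  - substituent
  - parent
  - ester_acyl
  output:
  - 1
  - '-'
  - 2
  - 3
  - 4
  - 0
  - 酯
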