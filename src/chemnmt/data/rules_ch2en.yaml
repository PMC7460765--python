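# Demonstration rule set for the three-stage rule-based translator.
# Covers only the package's toy nomenclature grammar; it is an open
# stand-in illustrating the disassembly/translation/reassembly
# architecture, not a production rule set.
direction: Ch2En
aromatic_parents:
- 苯
ester_triggers:
- 甲酯
- 乙酯
- 丙酯
- 丁酯
- 戊酯
- 己酯
- 庚酯
- 辛酯
- 壬酯
- 癸酯
builtin_locants: true
lexicon:
- text: 甲
  role: parent
- text: 甲胺
  role: parent
- text: 甲基
  role: substituent
- text: 甲酸
  role: ester_acyl
- text: 甲酯
  role: ester_alkyl
- text: 乙
  role: parent
- text: 乙胺
  role: parent
- text: 乙基
  role: substituent
- text: 乙酸
  role: ester_acyl
- text: 乙酯
  role: ester_alkyl
- text: 丙
  role: parent
- text: 丙胺
  role: parent
- text: 丙基
  role: substituent
- text: 丙酸
  role: ester_acyl
- text: 丙酯
  role: ester_alkyl
- text: 丁
  role: parent
- text: 丁胺
  role: parent
- text: 丁基
  role: substituent
- text: 丁酸
  role: ester_acyl
- text: 丁酯
  role: ester_alkyl
- text: 戊
  role: parent
- text: 戊胺
  role: parent
- text: 戊基
  role: substituent
- text: 戊酸
  role: ester_acyl
- text: 戊酯
  role: ester_alkyl
- text: 己
  role: parent
- text: 己胺
  role: parent
- text: 己基
  role: substituent
- text: 己酸
  role: ester_acyl
- text: 己酯
  role: ester_alkyl
- text: 庚
  role: parent
- text: 庚胺
  role: parent
- text: 庚基
  role: substituent
- text: 庚酸
  role: ester_acyl
- text: 庚酯
  role: ester_alkyl
- text: 辛
  role: parent
- text: 辛胺
  role: parent
- text: 辛基
  role: substituent
- text: 辛酸
  role: ester_acyl
- text: 辛酯
  role: ester_alkyl
- text: 壬
  role: parent
- text: 壬胺
  role: parent
- text: 壬基
  role: substituent
- text: 壬酸
  role: ester_acyl
- text: 壬酯
  role: ester_alkyl
- text: 癸
  role: parent
- text: 癸胺
  role: parent
- text: 癸基
  role: substituent
- text: 癸酸
  role: ester_acyl
- text: 癸酯
  role: ester_alkyl
- text: 氯
  role: substituent
- text: 溴
  role: substituent
- text: 氟
  role: substituent
- text: 碘
  role: substituent
- text: 胺
  role: suffix
- text: 苯
  role: parent
- text: 烷
  role: suffix
- text: 醇
  role: suffix
- text: 酚
  role: suffix
- text: 二
  role: multiplier
- text: 三
  role: multiplier
- text: '-'
  role: punctuation
dictionary:
- text: 甲
  role: parent
  context: default
  translation: methan
- text: 甲胺
  role: parent
  context: default
  translation: methylamine
- text: 甲基
  role: substituent
  context: default
  translation: methyl
- text: 甲酸
  role: ester_acyl
  context: default
  translation: methanoic acid
- text: 甲酸
  role: ester_acyl
  context: ester
  translation: formate
- text: 甲酯
  role: ester_alkyl
  context: default
  translation: methyl
- text: 乙
  role: parent
  context: default
  translation: ethan
- text: 乙胺
  role: parent
  context: default
  translation: ethylamine
- text: 乙基
  role: substituent
  context: default
  translation: ethyl
- text: 乙酸
  role: ester_acyl
  context: default
  translation: ethanoic acid
- text: 乙酸
  role: ester_acyl
  context: ester
  translation: acetate
- text: 乙酯
  role: ester_alkyl
  context: default
  translation: ethyl
- text: 丙
  role: parent
  context: default
  translation: propan
- text: 丙胺
  role: parent
  context: default
  translation: propylamine
- text: 丙基
  role: substituent
  context: default
  translation: propyl
- text: 丙酸
  role: ester_acyl
  context: default
  translation: propanoic acid
- text: 丙酸
  role: ester_acyl
  context: ester
  translation: propanoate
- text: 丙酯
  role: ester_alkyl
  context: default
  translation: propyl
- text: 丁
  role: parent
  context: default
  translation: butan
- text: 丁胺
  role: parent
  context: default
  translation: butylamine
- text: 丁基
  role: substituent
  context: default
  translation: butyl
- text: 丁酸
  role: ester_acyl
  context: default
  translation: butanoic acid
- text: 丁酸
  role: ester_acyl
  context: ester
  translation: butanoate
- text: 丁酯
  role: ester_alkyl
  context: default
  translation: butyl
- text: 戊
  role: parent
  context: default
  translation: pentan
- text: 戊胺
  role: parent
  context: default
  translation: pentylamine
- text: 戊基
  role: substituent
  context: default
  translation: pentyl
- text: 戊酸
  role: ester_acyl
  context: default
  translation: pentanoic acid
- text: 戊酸
  role: ester_acyl
  context: ester
  translation: pentanoate
- text: 戊酯
  role: ester_alkyl
  context: default
  translation: pentyl
- text: 己
  role: parent
  context: default
  translation: hexan
- text: 己胺
  role: parent
  context: default
  translation: hexylamine
- text: 己基
  role: substituent
  context: default
  translation: hexyl
- text: 己酸
  role: ester_acyl
  context: default
  translation: hexanoic acid
- text: 己酸
  role: ester_acyl
  context: ester
  translation: hexanoate
- text: 己酯
  role: ester_alkyl
  context: default
  translation: hexyl
- text: 庚
  role: parent
  context: default
  translation: heptan
- text: 庚胺
  role: parent
  context: default
  translation: heptylamine
- text: 庚基
  role: substituent
  context: default
  translation: heptyl
- text: 庚酸
  role: ester_acyl
  context: default
  translation: heptanoic acid
- text: 庚酸
  role: ester_acyl
  context: ester
  translation: heptanoate
- text: 庚酯
  role: ester_alkyl
  context: default
  translation: heptyl
- text: 辛
  role: parent
  context: default
  translation: octan
- text: 辛胺
  role: parent
  context: default
  translation: octylamine
- text: 辛基
  role: substituent
  context: default
  translation: octyl
- text: 辛酸
  role: ester_acyl
  context: default
  translation: octanoic acid
- text: 辛酸
  role: ester_acyl
  context: ester
  translation: octanoate
- text: 辛酯
  role: ester_alkyl
  context: default
  translation: octyl
- text: 壬
  role: parent
  context: default
  translation: nonan
- text: 壬胺
  role: parent
  context: default
  translation: nonylamine
- text: 壬基
  role: substituent
  context: default
  translation: nonyl
- text: 壬酸
  role: ester_acyl
  context: default
  translation: nonanoic acid
- text: 壬酸
  role: ester_acyl
  context: ester
  translation: nonanoate
- text: 壬酯
  role: ester_alkyl
  context: default
  translation: nonyl
- text: 癸
  role: parent
  context: default
  translation: decan
- text: 癸胺
  role: parent
  context: default
  translation: decylamine
- text: 癸基
  role: substituent
  context: default
  translation: decyl
- text: 癸酸
  role: ester_acyl
  context: default
  translation: decanoic acid
- text: 癸酸
  role: ester_acyl
  context: ester
  translation: decanoate
- text: 癸酯
  role: ester_alkyl
  context: default
  translation: decyl
- text: 氯
  role: substituent
  context: default
  translation: chloro
- text: 溴
  role: substituent
  context: default
  translation: bromo
- text: 氟
  role: substituent
  context: default
  translation: fluoro
- text: 碘
  role: substituent
  context: default
  translation: iodo
- text: 胺
  role: suffix
  context: default
  translation: amine
- text: 苯
  role: parent
  context: default
  translation: benzene
- text: 烷
  role: suffix
  context: default
  translation: e
- text: 醇
  role: suffix
  context: default
  translation: ol
- text: 酚
  role: suffix
  context: default
  translation: ol
- text: 二
  role: multiplier
  context: default
  translation: di
- text: 三
  role: multiplier
  context: default
  translation: tri
- text: '-'
  role: punctuation
  context: default
  translation: '-'
templates:
- match:
  - ester_acyl
  - ester_alkyl
  output:
  - 1
  - ' '
  - 0
- match:
  - locant
  - substituent
  - ester_acyl
  - ester_alkyl
  output:
  - 3
  - ' '
  - 0
  - '-'
  - 1
  - 2
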