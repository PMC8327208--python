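"""Static 45-direction sphere design used for surface-averaging kurtosis.

Antipodally non-duplicated set whose symmetrized 90-point counterpart is
a spherical 11-design: equal-weight averaging integrates polynomials up
to degree 11 exactly (all spherical-harmonic moments of degree 1-11
vanish to ~1e-14 at full precision; the 16-decimal table printed here
retains them below 1e-9). Constructed by numerically zeroing the
even-degree harmonic moments; see scripts/make_sphere_design.py for the
generator and the verification of the design property.
"""

import numpy as np

SPHERE45 = np.array([
    [+0.4646809549156546, +0.8852857796975584, +0.0184580173356057],
    [+0.7618288520120440, +0.6459411797728587, +0.0487523590778819],
    [-0.2501401688614869, +0.9594997829682853, +0.1295764731954082],
    [+0.9805239418494976, +0.1436607240890171, +0.1339193631038552],
    [+0.9792540998693158, -0.1448302369399456, +0.1417237113437813],
    [+0.7568856947124121, -0.6355480294631080, +0.1523244805842768],
    [-0.9336009626992838, -0.3238747956053382, +0.1532786978629805],
    [-0.6068742500112174, +0.7770761721553934, +0.1669019692563385],
    [-0.9276617126669362, +0.3324829943271655, +0.1699964862433596],
    [+0.1706732869419216, +0.9697938139505815, +0.1742715913384204],
    [+0.4091921647541331, -0.8947156961806784, +0.1790128356061391],
    [-0.0016574743825559, -0.9815741151837435, +0.1910746167860148],
    [-0.6891928298896829, -0.6608252949859246, +0.2971921478360698],
    [-0.3262726953860333, -0.8891118107140245, +0.3209771273694771],
    [+0.8325038581593472, -0.4508055994404279, +0.3220429127662304],
    [+0.8326373539622222, +0.4409949455043740, +0.3350201409264574],
    [-0.7324958864035933, +0.5749387893060790, +0.3645478911653094],
    [-0.9169409452595552, +0.1256273326728897, +0.3787308756782429],
    [+0.5394167317661093, +0.7410881675161726, +0.3997723320319836],
    [-0.8681619326048934, -0.2318721275516351, +0.4387826059000228],
    [-0.0633379513744254, +0.8922480249455839, +0.4470813862110519],
    [+0.3950299948547861, -0.7804161414572756, +0.4846668436338157],
    [-0.3829257006945749, +0.7542695216283689, +0.5333342258753700],
    [+0.0128028582445505, -0.8425739963981678, +0.5384284050961561],
    [+0.8371681503028378, +0.0194804743387337, +0.5465985722978640],
    [+0.2964888773265069, +0.7700103963027682, +0.5649587022139949],
    [-0.5733173695191182, -0.5771695617103003, +0.5815345998672982],
    [+0.6857400148883346, +0.3870965655424359, +0.6163739781384329],
    [+0.5626485544629162, -0.5445745202238278, +0.6219848841280459],
    [+0.7376655912904881, -0.1737763471692286, +0.6524195403193979],
    [-0.6998733866760543, +0.2082971023765423, +0.6832199936800200],
    [-0.2849160154868166, -0.6611689528120067, +0.6940306044812364],
    [-0.5248291290080129, +0.4589413943361995, +0.7168871472619909],
    [-0.6646815272700849, -0.1894993816652485, +0.7226952688750604],
    [-0.1262236369491683, +0.6269352266272342, +0.7687781312506119],
    [+0.1251205375510647, -0.5912778820174734, +0.7967027785315320],
    [+0.2492067276300695, +0.5310691523678770, +0.8098528028643088],
    [+0.4720867799263243, +0.2654942336605984, +0.8406229143389834],
    [+0.4037623952280731, -0.3210464893305546, +0.8566826016023761],
    [-0.3950496529854496, -0.2613358833152167, +0.8807038819988994],
    [-0.3796189938471575, +0.1332525894769926, +0.9154961315637264],
    [-0.0611804081483447, -0.3555855511835305, +0.9326391978939694],
    [+0.3593070303865296, -0.0074952842113645, +0.9331893048194478],
    [-0.0702244099570399, +0.3315649486717125, +0.9408151875148011],
    [-0.0000000002057372, +0.0000000022377251, +1.0000000000000000],
])
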